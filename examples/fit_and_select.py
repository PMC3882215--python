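"""Fit the six rate families to a simulated tree and rank them by AICc.

Simulates one birth-death tree with known rates, fits all six families
under complete sampling, and prints the selection table.
"""

from bdiv import (
    MODEL_IDS,
    SamplingScheme,
    SimulationSpec,
    make_model,
    select_model,
    simulate_reconstructed,
)

truth = make_model("M3", [1.0, 0.5])  # constant-rate birth-death
tree = simulate_reconstructed(SimulationSpec(
    model=truth, conditioning="age", value=8.0, replicates=1, seed=5))[0]
print(f"simulated tree: {tree.m} tips, age {tree.age} (truth: M3, lam=1.0, mu=0.5)")

candidates = [(mid, SamplingScheme("complete")) for mid in MODEL_IDS]
table = select_model(tree, candidates, criterion="AICc", restarts=5, seed=0)
cols = ["model_id", "k", "loglik", "AICc", "dAICc", "best", "params"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))

best = table.loc[table.best, "model_id"].item()
print(
    f"\nAICc prefers {best}; models within ~2 AICc units of the best are "
    "statistically indistinguishable on a single tree, and nested families "
    "can only improve the raw log-likelihood."
)
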
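"""Evaluate tree likelihoods under the three taxon-sampling schemes.

Builds a small chronogram from a Newick string and compares the
log-likelihood of a constant-rate birth-death model under complete,
uniform and diversified sampling assumptions.
"""

from bdiv import (
    SamplingScheme,
    loglik_complete,
    loglik_diversified,
    loglik_uniform,
    make_model,
    read_newick,
    to_reconstructed,
)

newick = "((((A:0.5,B:0.5):0.7,C:1.2):0.5,D:1.7):0.3,E:2);"
record = read_newick(newick)
model = make_model("M3", [1.0, 0.5])  # speciation 1.0, extinction 0.5 per lineage

complete = to_reconstructed(record)
print(f"tree: {complete.m} tips, age {complete.age}, "
      f"divergence times {complete.divergence_times.tolist()}")

ll_complete = loglik_complete(complete, model)
print(f"log L (complete sampling, n = m = 5):      {ll_complete:+.4f}")

# suppose only half of the clade's species were sequenced
sparse = to_reconstructed(record, total_species=10)
ll_uniform = loglik_uniform(sparse, model, rho=0.5)
ll_diversified = loglik_diversified(sparse, model)
print(f"log L (uniform sampling, rho = 0.5):       {ll_uniform:+.4f}")
print(f"log L (diversified sampling, n = 10):      {ll_diversified:+.4f}")

print(
    "\nThe three values are densities of the same divergence times under "
    "different sampling assumptions; under diversified sampling the five "
    "missing speciation events must all postdate the youngest observed "
    "split, which here makes that assumption the least favourable."
)
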
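"""Deterministic test trees and simulation regimes.

Everything every test needs is generated here, with no downloads: small
hand-built chronograms with analytically known summaries, and the three
generating regimes of the simulation studies (constant-rate pure birth,
constant-rate birth-death, and a decreasing-speciation birth-death), with
parameters chosen so the expected diversity at the process age is
approximately 200 species, plus small-tree variants at roughly 20 species
for the bias study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .likelihood import ReconstructedTree, SamplingScheme
from .models import RateModel, expected_diversity, make_model
from .simulator import SimulationSpec, simulate_reconstructed

__all__ = ["Regime", "make_study_regimes", "make_hand_fixtures", "HAND_NEWICKS"]


@dataclass(frozen=True)
class Regime:
    """A generating model plus the process age it is run for."""

    name: str
    model: RateModel
    age: float

    def expected_tips(self) -> float:
        """Expected clade size from the MRCA, conditioned on survival of
        both root lineages (twice the single-lineage conditional mean)."""
        return 2.0 * expected_diversity(self.model, 0.0, self.age,
                                        conditioned_on_survival=True)

    def simulate(self, replicates: int, seed: int,
                 scheme: Optional[SamplingScheme] = None) -> List[ReconstructedTree]:
        spec = SimulationSpec(
            model=self.model, conditioning="age", value=self.age,
            scheme=scheme or SamplingScheme("complete"),
            replicates=replicates, seed=seed,
        )
        return simulate_reconstructed(spec)


def make_study_regimes(seed: int = 0) -> Dict[str, Regime]:
    """The generating regimes of the simulation studies.

    Ages solve E[N | survival] = 200 (or 20 for the ``_small`` variants)
    exactly for the closed-form models and to three decimals for the
    decreasing-speciation regime.
    """
    ln = np.log
    regimes = {
        # Yule: E = 2 e^{lam T}; lam T = ln 100 -> 200 species
        "pure_birth": Regime("pure_birth", make_model("M1", [ln(100.0) / 10.0]), 10.0),
        "pure_birth_small": Regime(
            "pure_birth_small", make_model("M1", [ln(10.0) / 10.0]), 10.0
        ),
        # constant-rate birth-death: E = 2 (lam e^{bT} - mu) / b with b = lam - mu
        "birth_death": Regime(
            "birth_death", make_model("M3", [1.0, 0.5]), 2.0 * ln(50.5)
        ),
        "birth_death_small": Regime(
            "birth_death_small", make_model("M3", [1.0, 0.5]), 2.0 * ln(5.5)
        ),
        # decreasing speciation rate with extinction: lam(t) = 0.5 e^{-0.1 t} + 0.1;
        # age solved numerically for E ~= 200 (see _solve_age_for_diversity)
        "decreasing_bd": Regime(
            "decreasing_bd",
            make_model("M5", [0.5, 0.1, 0.1]),
            _solve_age_for_diversity(make_model("M5", [0.5, 0.1, 0.1]), 200.0),
        ),
        "decreasing_bd_small": Regime(
            "decreasing_bd_small",
            make_model("M5", [0.5, 0.1, 0.1]),
            _solve_age_for_diversity(make_model("M5", [0.5, 0.1, 0.1]), 20.0),
        ),
    }
    return regimes


def _solve_age_for_diversity(model: RateModel, target: float) -> float:
    """Age at which the survival-conditioned expected clade size hits ``target``."""
    from scipy.optimize import brentq

    def f(T):
        return 2.0 * expected_diversity(model, 0.0, T, True) - target

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("expected diversity never reaches target")
    return float(brentq(f, 1e-6, hi, xtol=1e-10))


#: Hand-built Newick chronograms with hand-checkable summaries.
HAND_NEWICKS = {
    # 3 tips, divergence times since MRCA {0, 1}, age 2
    "three_tip": "((A:1,B:1):1,C:2);",
    # non-ultrametric and polytomous variants for error-path tests
    "non_ultrametric": "((A:1,B:2):1,C:2);",
    "polytomy": "(A:1,B:1,C:1);",
    # 4 tips, times {0, 0.5, 1.2}, age 2
    "four_tip": "(((A:0.8,B:0.8):0.7,C:1.5):0.5,D:2);",
    # 5 tips, times {0, 0.3, 0.8, 1.5}, age 2
    "five_tip": "((((A:0.5,B:0.5):0.7,C:1.2):0.5,D:1.7):0.3,E:2);",
}


def make_hand_fixtures() -> Dict[str, ReconstructedTree]:
    """The hand-built trees as ReconstructedTree objects (complete sampling)."""
    return {
        "three_tip": ReconstructedTree(np.array([0.0, 1.0]), 2.0),
        "four_tip": ReconstructedTree(np.array([0.0, 0.5, 1.2]), 2.0),
        "five_tip": ReconstructedTree(np.array([0.0, 0.3, 0.8, 1.5]), 2.0),
        # snake-style sparse sampling: 41 of ~3500 species
        "snake_style": ReconstructedTree(
            np.concatenate([[0.0], np.linspace(0.08, 0.62, 39)]) * 169.7,
            169.7,
            n=3500,
        ),
    }
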
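"""Parametric-bootstrap model adequacy testing.

Three summary statistics are compared between the observed tree and trees
simulated under the fitted model (with the fitted sampling scheme applied
before statistics are computed, so the null matches the observation
process):

* the Pybus-Harvey gamma statistic (age-conditioned simulations),
* the number of sampled taxa (age-conditioned simulations),
* the tree age (taxa-conditioned simulations).

Empirical p-values are two-sided equal-tail probabilities,
``p = 2 * min(r, 1 - r)`` with ``r`` the fraction of null draws at or
below the observation, clamped to ``[2 / (n_sims + 1), 1]``; the one-sided
tails are reported alongside.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import ProcessWindow, SpeciationTimeDistribution, log_q
from .inference import MLEResult
from .likelihood import ReconstructedTree, SamplingScheme
from .simulator import draw_age_given_taxa, _draw_total_tips

__all__ = ["AdequacyReport", "gamma_statistic", "bootstrap_adequacy"]


def gamma_statistic(tree: ReconstructedTree) -> float:
    """Pybus-Harvey gamma from the internode intervals of an ultrametric tree.

    Negative values indicate divergence events concentrated early (as under
    a slowing speciation rate); under a constant-rate pure-birth process
    gamma is asymptotically standard normal.
    """
    return _gamma_from_times(tree.divergence_times, tree.age)


def _gamma_from_times(times: np.ndarray, age: float) -> float:
    m = times.size + 1
    if m < 3:
        raise ValueError("gamma statistic requires at least 3 tips")
    bounds = np.concatenate([times, [age]])
    g = np.diff(bounds)  # g[j] = interval with j+2 lineages, j = 0..m-2
    j = np.arange(2, m + 1)
    weighted = j * g
    total = weighted.sum()
    cum = np.cumsum(weighted)[:-1]  # sum_{k=2}^{i} k g_k for i = 2..m-1
    mean_cum = cum.sum() / (m - 2)
    return float((mean_cum - total / 2.0) / (total * np.sqrt(1.0 / (12.0 * (m - 2)))))


@dataclass
class AdequacyReport:
    model_id: str
    scheme: SamplingScheme
    n_sims_age_conditioned: int
    n_sims_taxa_conditioned: int
    gamma_obs: float
    gamma_null: np.ndarray = field(repr=False)
    taxa_obs: int
    taxa_null: np.ndarray = field(repr=False)
    age_obs: float
    age_null: np.ndarray = field(repr=False)
    p_gamma: float = 0.0
    p_taxa: float = 0.0
    p_age: float = 0.0
    p_gamma_lower: float = 0.0
    p_taxa_lower: float = 0.0
    p_age_lower: float = 0.0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "scheme": self.scheme.kind,
            "rho": self.scheme.rho,
            "n_sims_age_conditioned": self.n_sims_age_conditioned,
            "n_sims_taxa_conditioned": self.n_sims_taxa_conditioned,
            "gamma_obs": self.gamma_obs,
            "taxa_obs": self.taxa_obs,
            "age_obs": self.age_obs,
            "p_gamma": self.p_gamma,
            "p_taxa": self.p_taxa,
            "p_age": self.p_age,
            "p_gamma_lower": self.p_gamma_lower,
            "p_taxa_lower": self.p_taxa_lower,
            "p_age_lower": self.p_age_lower,
            "gamma_null": self.gamma_null.tolist(),
            "taxa_null": self.taxa_null.tolist(),
            "age_null": self.age_null.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AdequacyReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            model_id=d["model_id"],
            scheme=SamplingScheme(d["scheme"], d["rho"]),
            n_sims_age_conditioned=d["n_sims_age_conditioned"],
            n_sims_taxa_conditioned=d["n_sims_taxa_conditioned"],
            gamma_obs=d["gamma_obs"],
            gamma_null=np.asarray(d["gamma_null"]),
            taxa_obs=d["taxa_obs"],
            taxa_null=np.asarray(d["taxa_null"]),
            age_obs=d["age_obs"],
            age_null=np.asarray(d["age_null"]),
            p_gamma=d["p_gamma"], p_taxa=d["p_taxa"], p_age=d["p_age"],
            p_gamma_lower=d["p_gamma_lower"], p_taxa_lower=d["p_taxa_lower"],
            p_age_lower=d["p_age_lower"],
        )


def empirical_p(null: np.ndarray, observed: float, n_sims: int):
    """(two-sided, lower-tail) empirical p-values with boundary clamping."""
    null = null[np.isfinite(null)]
    if null.size == 0 or np.all(null == null[0]):
        warnings.warn("degenerate null distribution; p reported at boundary")
        return 2.0 / (n_sims + 1), 1.0 / (n_sims + 1)
    r = float(np.mean(null <= observed))
    two = float(np.clip(2.0 * min(r, 1.0 - r), 2.0 / (n_sims + 1), 1.0))
    return two, max(r, 1.0 / (n_sims + 1))


def _simulate_sampled_times(model, T: float, scheme: SamplingScheme,
                            reps: int, rng: np.random.Generator):
    """Fast age-conditioned null draws of (sampled divergence times, m).

    Uniform sampling uses the rho-modified i.i.d. representation of the
    sampled tree (conditioned on the sampled MRCA age, matching the
    likelihood's conditioning); diversified sampling prunes the youngest
    events of a complete simulation.
    """
    out = []
    if scheme.kind == "uniform":
        counts = _draw_total_tips(model, T, rng, reps, rho=scheme.rho)
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T), rho=scheme.rho)
    else:
        counts = _draw_total_tips(model, T, rng, reps)
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T))
    # draw all times in one vectorized call, then split per replicate
    sizes = counts - 2
    pool = dist.rvs(int(sizes.sum()), rng) if sizes.sum() else np.empty(0)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for i in range(reps):
        extra = np.sort(pool[offsets[i]:offsets[i + 1]])
        times = np.concatenate([[0.0], extra])
        m = int(counts[i])
        if scheme.kind == "diversified":
            keep = max(2, int(round(scheme.rho * m)))
            if keep < m:
                times = times[: keep - 1]
                m = keep
        out.append((times, m))
    return out


def bootstrap_adequacy(
    tree: ReconstructedTree,
    mle: MLEResult,
    n_sims: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> AdequacyReport:
    """Parametric bootstrap of gamma, tip count and tree age under the MLE.

    ``n_sims`` trees are simulated conditioning on the observed age (gamma
    and tip-count nulls) and another ``n_sims`` conditioning on the
    observed number of sampled taxa (age null).
    """
    if not mle.converged:
        raise ValueError("refusing to bootstrap from a non-converged MLE")
    if n_sims < 100:
        raise ValueError("n_sims >= 100 required for meaningful p-values")
    if rng is None:
        rng = np.random.default_rng(seed)
    model, scheme = mle.model, mle.scheme

    draws = _simulate_sampled_times(model, tree.age, scheme, n_sims, rng)
    gamma_null = np.array([
        _gamma_from_times(t, tree.age) if m >= 3 else np.nan for t, m in draws
    ])
    taxa_null = np.array([m for _, m in draws], dtype=float)

    if scheme.kind == "uniform":
        age_null = draw_age_given_taxa(model, tree.m, n_sims, rng, rho=scheme.rho)
    else:
        n_total = tree.m if scheme.kind == "complete" else max(
            tree.m, int(round(tree.m / scheme.rho))
        )
        age_null = draw_age_given_taxa(model, n_total, n_sims, rng)

    gamma_obs = gamma_statistic(tree)
    p_gamma, p_gamma_lo = empirical_p(gamma_null, gamma_obs, n_sims)
    p_taxa, p_taxa_lo = empirical_p(taxa_null, tree.m, n_sims)
    p_age, p_age_lo = empirical_p(age_null, tree.age, n_sims)

    return AdequacyReport(
        model_id=mle.model_id,
        scheme=scheme,
        n_sims_age_conditioned=n_sims,
        n_sims_taxa_conditioned=n_sims,
        gamma_obs=gamma_obs,
        gamma_null=gamma_null,
        taxa_obs=tree.m,
        taxa_null=taxa_null,
        age_obs=tree.age,
        age_null=age_null,
        p_gamma=p_gamma, p_taxa=p_taxa, p_age=p_age,
        p_gamma_lower=p_gamma_lo, p_taxa_lower=p_taxa_lo, p_age_lower=p_age_lo,
    )
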
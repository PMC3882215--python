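"""Reconstructed-tree log-likelihoods under three taxon-sampling schemes.

A reconstructed tree is summarized by its ordered divergence times
(measured forward from the most recent common ancestor, whose time is 0),
its age ``T``, the number of sampled tips ``m`` and the number of extant
species in the clade ``n`` (sampled plus missing).  The process starts
with two lineages at the MRCA and, by default, every likelihood is
conditioned on both of them having sampled descendants ("survival"), which
is what makes the MRCA observable in the first place.

With ``q`` the geometric parameter of :mod:`bdiv.core` the likelihoods are
densities of the ordered divergence times (and, for uniform/diversified
sampling, of the tip/species count):

* complete / uniform(rho):
  ``(m-1)! * (m-1) * q(0)^2 * prod_i lambda(t_i) rho e^{r(t_i,T)} / D(t_i)^2``
* diversified, given n:
  ``(n-2)!/(n-m)! * prod_i f(t_i) * (1 - F(t_star))^(n-m)`` where
  ``t_star`` is the most recent observed speciation time and all n-m
  unobserved speciation events must fall after it;
* diversified, given only the MRCA age:
  the given-n density times ``(n-1) q(0)^2 (1-q(0))^(n-2)``, the
  geometric law of the total species count.

The conventions are chosen so that all three coincide exactly at rho = 1.
The constant topology probability is omitted throughout; it cancels in
every model or sampling-scheme comparison on a fixed tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .core import ProcessWindow, SpeciationTimeDistribution, _check_rho, _log_D, log_q
from .models import RateModel

__all__ = [
    "ReconstructedTree",
    "SamplingScheme",
    "loglik_complete",
    "loglik_uniform",
    "loglik_diversified_given_n",
    "loglik_diversified",
    "loglik",
]


@dataclass(frozen=True)
class ReconstructedTree:
    """Divergence-time summary of an ultrametric reconstructed tree.

    ``divergence_times`` holds the m-1 speciation times since the MRCA in
    ascending order; the first entry is the MRCA itself at time 0.  ``n``
    is the known number of extant species in the clade (n >= m); for
    completely sampled trees n == m.
    """

    divergence_times: np.ndarray
    age: float
    n: Optional[int] = None
    topology: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        times = np.sort(np.asarray(self.divergence_times, dtype=float))
        object.__setattr__(self, "divergence_times", times)
        if times.size < 1:
            raise ValueError("a reconstructed tree needs at least the MRCA event (m >= 2)")
        if abs(times[0]) > 1e-9 * max(self.age, 1.0):
            raise ValueError("earliest divergence time must be 0 (the MRCA)")
        if times[0] != 0.0:
            times[0] = 0.0
        if np.any(times < 0.0) or np.any(times > self.age * (1 + 1e-12)):
            raise ValueError("divergence times must lie in [0, age]")
        if self.n is None:
            object.__setattr__(self, "n", self.m)
        if self.n < self.m:
            raise ValueError(f"total species n={self.n} < sampled tips m={self.m}")

    @property
    def m(self) -> int:
        """Number of sampled tips."""
        return self.divergence_times.size + 1

    @property
    def sampling_fraction(self) -> float:
        return self.m / self.n

    @property
    def t_star(self) -> float:
        """Most recent observed speciation time (the diversified cut point)."""
        return float(self.divergence_times[-1])


@dataclass(frozen=True)
class SamplingScheme:
    """Which likelihood applies: complete, uniform(rho) or diversified(rho)."""

    kind: str
    rho: float = 1.0

    def __post_init__(self):
        if self.kind not in ("complete", "uniform", "diversified"):
            raise ValueError(f"unknown sampling scheme {self.kind!r}")
        _check_rho(self.rho)
        if self.kind == "complete" and self.rho != 1.0:
            raise ValueError("complete sampling requires rho = 1")


def _times_term(model: RateModel, tree: ReconstructedTree, rho: float) -> float:
    """Sum over non-root events of log(lambda(t) rho e^{r(t,T)} / D(t)^2)."""
    t = tree.divergence_times[1:]
    if t.size == 0:
        return 0.0
    T = tree.age
    with np.errstate(divide="ignore"):
        terms = (
            np.log(model.lambda_t(t))
            + np.log(rho)
            + model.r_integral(t, T)
            - 2.0 * _log_D(model, t, T, rho)
        )
    return float(np.sum(terms))


def loglik_uniform(
    tree: ReconstructedTree,
    model: RateModel,
    rho: float,
    condition_on_survival: bool = True,
) -> float:
    """Log-density of the tree under uniform taxon sampling with fraction rho.

    Identical to :func:`loglik_complete` at rho = 1.
    """
    rho = _check_rho(rho)
    m, T = tree.m, tree.age
    lq0 = float(log_q(model, np.float64(0.0), T, rho))
    ll = np.log(m - 1) + gammaln(m - 1) + 2.0 * lq0 + _times_term(model, tree, rho)
    if not condition_on_survival:
        ll += 2.0 * (np.log(rho) - float(_log_D(model, np.float64(0.0), T, rho)))
    return float(ll)


def loglik_complete(
    tree: ReconstructedTree, model: RateModel, condition_on_survival: bool = True
) -> float:
    """Log-density under complete sampling (requires n == m)."""
    if tree.n != tree.m:
        raise ValueError(
            f"complete sampling requires n == m, got n={tree.n}, m={tree.m}"
        )
    return loglik_uniform(tree, model, 1.0, condition_on_survival)


def _resolve_n(tree: ReconstructedTree, rho: Optional[float]) -> int:
    if rho is None:
        return int(tree.n)
    _check_rho(rho)
    if tree.n > tree.m:
        return int(tree.n)
    n_float = tree.m / rho
    n = int(round(n_float))
    if abs(n_float - n) > 1e-6:
        warnings.warn(
            f"m/rho = {n_float:.4f} is not integral; using n = {n}", stacklevel=3
        )
    return n


def loglik_diversified_given_n(tree: ReconstructedTree, model: RateModel) -> float:
    """Log-density under diversified sampling, conditioned on the MRCA age
    and the total species count n.

    The n - m unobserved speciation events each fall after the most recent
    observed one (time ``t_star``) and contribute a factor
    ``1 - F(t_star)``, accumulated via log1p for numerical safety.
    """
    n, m, T = int(tree.n), tree.m, tree.age
    if n < m:
        raise ValueError("n < m")
    dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T), rho=1.0)
    t_nr = tree.divergence_times[1:]
    obs = float(np.sum(dist.log_density(t_nr))) if t_nr.size else 0.0
    missing = (n - m) * float(dist.log_sf(np.float64(tree.t_star)))
    comb = float(gammaln(n - 1) - gammaln(n - m + 1))
    return comb + obs + missing


def loglik_diversified(
    tree: ReconstructedTree,
    model: RateModel,
    rho: Optional[float] = None,
    condition_on_survival: bool = True,
) -> float:
    """Log-density under diversified sampling, conditioned only on the MRCA age.

    The total species count is handled through the geometric law of N(T):
    the given-n density is multiplied by P(N = n | MRCA, survival).  When
    ``rho`` is given and the tree does not carry an explicit n, the species
    count is n = round(m / rho).
    """
    n = _resolve_n(tree, rho)
    T = tree.age
    if n == tree.n:
        tree_n = tree
    else:
        tree_n = ReconstructedTree(tree.divergence_times, T, n=n)
    lq0 = float(log_q(model, np.float64(0.0), T, 1.0))
    count_term = np.log(n - 1) + 2.0 * lq0 + (n - 2) * np.log1p(-np.exp(lq0))
    ll = count_term + loglik_diversified_given_n(tree_n, model)
    if not condition_on_survival:
        ll += 2.0 * (-float(_log_D(model, np.float64(0.0), T, 1.0)))
    return float(ll)


def loglik(
    tree: ReconstructedTree,
    model: RateModel,
    scheme: SamplingScheme,
    condition_on_survival: bool = True,
) -> float:
    """Scheme-dispatching log-likelihood."""
    if scheme.kind == "complete":
        return loglik_complete(tree, model, condition_on_survival)
    if scheme.kind == "uniform":
        return loglik_uniform(tree, model, scheme.rho, condition_on_survival)
    return loglik_diversified(tree, model, scheme.rho, condition_on_survival)
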
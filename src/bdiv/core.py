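"""Core probability functions of the time-dependent birth-death process.

Everything here concerns a process started with a *single* lineage at time
``t0`` and observed at the present ``T``.  With

    r(s, t) = int_s^t (mu(x) - lambda(x)) dx
    A(s, T) = int_s^T mu(x) * exp(r(s, x)) dx

and a uniform sampling fraction ``rho`` applied to the tips at the present,
the building blocks are

    D(s)        = rho * (1 + A(s, T)) + (1 - rho) * exp(r(s, T))
    P_s(s, T)   = rho / D(s)                  # >= 1 sampled descendant
    q(s, T)     = exp(r(s, T)) / D(s)         # geometric parameter

The number of sampled descendants of a surviving lineage is geometric with
success parameter ``q``, so ``P(N = n) = P_s * q * (1 - q)^(n-1)`` for
``n >= 1``.  At ``rho = 1`` these reduce to the classical complete-sampling
formulas (Kendall; Nee et al.), e.g. ``P_s = 1 / (1 + A)``.

The i.i.d. density of a reconstructed-tree speciation time on a window
``[t0, T]`` follows from the identity ``dq(t)/dt = lambda(t) * rho *
exp(r(t, T)) / D(t)^2``:

    f(t) = lambda(t) * rho * exp(r(t,T)) / D(t)^2 / (1 - q(t0))
    F(t) = (q(t) - q(t0)) / (1 - q(t0))

All functions have log-space variants; products over hundreds of
speciation events are always accumulated in log space by the likelihood
layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import RateModel

__all__ = [
    "ProcessWindow",
    "SpeciationTimeDistribution",
    "p_survival",
    "p_n",
    "p_one",
    "speciation_time_density",
    "speciation_time_cdf",
    "inverse_cdf",
]


@dataclass(frozen=True)
class ProcessWindow:
    """A birth-death process run from one lineage at ``t0`` until ``T``."""

    model: RateModel
    t0: float
    T: float

    def __post_init__(self):
        if not (np.isfinite(self.t0) and np.isfinite(self.T)):
            raise ValueError("window endpoints must be finite")
        if self.T < self.t0:
            raise ValueError(f"T={self.T} must be >= t0={self.t0}")

    @property
    def span(self) -> float:
        return self.T - self.t0


def _check_rho(rho: float) -> float:
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"sampling fraction rho={rho} must be in (0, 1]")
    return float(rho)


def _log_D(model: RateModel, s, T: float, rho: float):
    """log D(s) with D = rho (1 + A) + (1 - rho) e^{r(s,T)}, overflow-safe."""
    s = np.asarray(s, dtype=float)
    A = model.extinction_weighted_integral(s, T)
    r = model.r_integral(s, T)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        term1 = np.log(rho) + np.log1p(A)
        if rho == 1.0:
            return term1
        return np.logaddexp(term1, np.log1p(-rho) + r)


def log_q(model: RateModel, s, T: float, rho: float = 1.0):
    """log of the geometric parameter q(s, T) under sampling fraction rho."""
    return model.r_integral(np.asarray(s, dtype=float), T) - _log_D(model, s, T, rho)


def log_q_ages(model: RateModel, ages, rho: float = 1.0):
    """log q(0, T) for a vector of candidate MRCA ages ``T``.

    Used by taxa-conditioned simulation, which scans many ages; the
    extinction-weighted integral from 0 is a single cumulative integral,
    so all ages share one quadrature pass.
    """
    ages = np.asarray(ages, dtype=float)
    r = model.r_integral(0.0, ages)
    if model.mu0 == 0.0:
        A = np.zeros_like(ages)
    elif model.b == 0.0:
        A = model.extinction_weighted_integral(np.zeros_like(ages), ages)
    else:
        t_max = float(np.max(ages))
        grid = np.linspace(0.0, t_max, 4097)
        integrand = model.mu0 * np.exp(model.r_integral(0.0, grid))
        G = np.concatenate([[0.0], np.cumsum(
            0.5 * (integrand[1:] + integrand[:-1]) * np.diff(grid))])
        A = np.interp(ages, grid, G)
    with np.errstate(over="ignore", divide="ignore"):
        if rho == 1.0:
            logD = np.log1p(A)
        else:
            logD = np.logaddexp(np.log(rho) + np.log1p(A), np.log1p(-rho) + r)
    return r - logD


def p_survival(window: ProcessWindow, rho: float = 1.0, log: bool = False):
    """Probability that the lineage has >= 1 (sampled) descendant at ``T``."""
    rho = _check_rho(rho)
    if window.span == 0.0:
        return 0.0 if log else 1.0
    lp = np.log(rho) - _log_D(window.model, np.float64(window.t0), window.T, rho)
    lp = float(lp)
    if not np.isfinite(lp) and lp > 0:
        raise FloatingPointError("non-finite survival integrand (diverging rates)")
    return lp if log else float(np.exp(lp))


def p_n(window: ProcessWindow, n, rho: float = 1.0, log: bool = False):
    """P(N(T) = n | N(t0) = 1): zero-modified geometric in the (sampled) tip count."""
    rho = _check_rho(rho)
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("n must be >= 0")
    if window.span == 0.0:
        p = np.where(n_arr == 1, 1.0, 0.0)
    else:
        lq = log_q(window.model, np.float64(window.t0), window.T, rho)
        lps = np.log(rho) - _log_D(window.model, np.float64(window.t0), window.T, rho)
        with np.errstate(divide="ignore"):
            log_geom = lps + lq + (n_arr - 1) * np.log1p(-np.exp(lq))
        p0 = -np.expm1(lps)  # 1 - p_survival
        p = np.where(n_arr == 0, p0, np.exp(log_geom))
    if log:
        with np.errstate(divide="ignore"):
            p = np.log(p)
    return float(p) if np.isscalar(n) else p


def p_one(window: ProcessWindow, rho: float = 1.0, log: bool = False):
    """P(N(T) = 1 | N(t0) = 1); identical to ``p_n(window, 1)``."""
    return p_n(window, 1, rho=rho, log=log)


class SpeciationTimeDistribution:
    """I.i.d. distribution of a reconstructed-tree speciation time.

    For a process whose most recent common ancestor sits at ``window.t0``,
    every non-root speciation time in the reconstructed tree is an
    independent draw from this distribution on ``[t0, T]``.
    """

    _GRID = 2049

    def __init__(self, window: ProcessWindow, rho: float = 1.0):
        if window.span <= 0.0:
            raise ValueError("degenerate window: no speciation-time mass when T == t0")
        self.window = window
        self.rho = _check_rho(rho)
        self.model = window.model
        self._q0 = float(np.exp(log_q(self.model, np.float64(window.t0), window.T, self.rho)))
        self._log1m_q0 = float(np.log1p(-self._q0))
        self._grid_t = None
        self._grid_F = None

    # -- exact evaluations ----------------------------------------------
    def _q(self, t):
        return np.exp(log_q(self.model, t, self.window.T, self.rho))

    def log_density(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.window.t0 - 1e-12) or np.any(t > self.window.T + 1e-12):
            raise ValueError("t outside the process window")
        logD = _log_D(self.model, t, self.window.T, self.rho)
        with np.errstate(divide="ignore"):
            return (
                np.log(self.model.lambda_t(t))
                + np.log(self.rho)
                + self.model.r_integral(t, self.window.T)
                - 2.0 * logD
                - self._log1m_q0
            )

    def density(self, t):
        return np.exp(self.log_density(t))

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < self.window.t0 - 1e-12) or np.any(t > self.window.T + 1e-12):
            raise ValueError("t outside the process window")
        return np.clip((self._q(t) - self._q0) / (1.0 - self._q0), 0.0, 1.0)

    def log_sf(self, t):
        """log(1 - F(t)) computed as log1p(-q(t)) - log1p(-q0), stable as F -> 1."""
        lq = log_q(self.model, np.asarray(t, dtype=float), self.window.T, self.rho)
        return np.log1p(-np.exp(lq)) - self._log1m_q0

    # -- inversion and sampling -----------------------------------------
    def _ensure_grid(self):
        if self._grid_t is None:
            w = self.window
            self._grid_t = np.linspace(w.t0, w.T, self._GRID)
            F = self.cdf(self._grid_t)
            F[0], F[-1] = 0.0, 1.0
            self._grid_F = np.maximum.accumulate(F)

    def inverse_cdf(self, u):
        """Quantile function; |F(t) - u| driven to ~1e-12 by Newton refinement."""
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr < 0.0) or np.any(u_arr > 1.0):
            raise ValueError("u must lie in [0, 1]")
        self._ensure_grid()
        w = self.window
        t = np.interp(u_arr, self._grid_F, self._grid_t)
        for _ in range(3):
            resid = self.cdf(t) - u_arr
            dens = np.maximum(self.density(t), 1e-300)
            t = np.clip(t - resid / dens, w.t0, w.T)
        return float(t) if np.isscalar(u) else t

    def rvs(self, size: int, rng: np.random.Generator):
        return self.inverse_cdf(rng.random(size))


def speciation_time_density(window: ProcessWindow, t, rho: float = 1.0):
    return SpeciationTimeDistribution(window, rho).density(t)


def speciation_time_cdf(window: ProcessWindow, t, rho: float = 1.0):
    return SpeciationTimeDistribution(window, rho).cdf(t)


def inverse_cdf(window: ProcessWindow, u, rho: float = 1.0):
    return SpeciationTimeDistribution(window, rho).inverse_cdf(u)
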
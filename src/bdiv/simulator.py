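"""Simulation of reconstructed trees under time-dependent birth-death models.

The simulator exploits the exchangeability of reconstructed-tree
speciation events: conditioned on the MRCA age ``T`` and survival of both
root lineages, the number of tips on each side of the root is an
independent geometric draw and the non-root divergence times are i.i.d.
from the speciation-time distribution.  Topology, which carries no rate
information, is attached (when requested) by splitting a uniformly chosen
extant lineage at each successive event -- the classical construction of
the uniform ranked tree shape.

Age-conditioned simulation fixes ``T``; taxa-conditioned simulation fixes
the tip count and draws the MRCA age from its induced distribution
``p(T | n) ∝ (n-1) q(T)^2 (1-q(T))^(n-2)`` numerically normalized on an
adaptive grid (the age law implied by the same process machinery, with a
flat prior over the age).

Uniform taxon sampling is performed as literal binomial thinning of the
tips of a simulated topology followed by pruning; diversified sampling
deterministically removes the tips created by the most recent speciation
events and therefore operates directly on the divergence times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import ProcessWindow, SpeciationTimeDistribution, log_q, log_q_ages
from .likelihood import ReconstructedTree, SamplingScheme
from .models import RateModel

__all__ = [
    "SimulationSpec",
    "simulate_reconstructed",
    "apply_uniform_sampling",
    "apply_diversified_sampling",
    "draw_age_given_taxa",
    "tree_to_newick",
]


# ---------------------------------------------------------------------------
# minimal topology representation


@dataclass
class _Node:
    time: float  # time since the original MRCA at which this node was created
    children: List["_Node"] = field(default_factory=list)
    tip_id: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children


def _assemble_topology(times: np.ndarray, age: float, rng: np.random.Generator) -> _Node:
    """Build a ranked topology for sorted divergence times (times[0] == 0)."""
    root = _Node(0.0)
    left, right = _Node(-1.0), _Node(-1.0)
    root.children = [left, right]
    active = [left, right]
    for t in times[1:]:
        i = rng.integers(len(active))
        node = active[i]
        node.time = t
        a, b = _Node(-1.0), _Node(-1.0)
        node.children = [a, b]
        active[i] = a
        active.append(b)
    for j, node in enumerate(active):
        node.time = age
        node.tip_id = j
    return root


def tree_to_newick(tree: ReconstructedTree, precision: int = 10) -> str:
    """Newick string for a simulated tree (requires an attached topology)."""
    root = tree.topology
    if root is None:
        raise ValueError("tree carries no topology; simulate with topology=True")

    def fmt(node: _Node, parent_time: float) -> str:
        bl = node.time - parent_time
        if node.is_tip:
            return f"t{node.tip_id}:{bl:.{precision}f}"
        inner = ",".join(fmt(c, node.time) for c in node.children)
        return f"({inner}):{bl:.{precision}f}"

    inner = ",".join(fmt(c, 0.0) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# core draws


def _draw_total_tips(model: RateModel, T: float, rng: np.random.Generator,
                     size: int, rho: float = 1.0) -> np.ndarray:
    """Total (sampled) tip count: sum of two independent survival-conditioned
    geometric subtree sizes, one per MRCA lineage."""
    q = float(np.exp(log_q(model, np.float64(0.0), T, rho)))
    return rng.geometric(q, size) + rng.geometric(q, size)


def draw_age_given_taxa(
    model: RateModel,
    n: int,
    size: int,
    rng: np.random.Generator,
    rho: float = 1.0,
    grid_points: int = 1024,
) -> np.ndarray:
    """Draw MRCA ages from p(T | n) ∝ (n-1) q(T)^2 (1 - q(T))^(n-2)."""
    if n < 2:
        raise ValueError("taxa conditioning requires n >= 2")

    def log_dens(T_vals):
        lq = log_q_ages(model, np.asarray(T_vals, dtype=float), rho)
        with np.errstate(divide="ignore"):
            return 2.0 * lq + (n - 2) * np.log1p(-np.exp(lq))

    # expand the age range until the density has decayed on both flanks
    t_hi = 1.0
    for _ in range(200):
        probe = np.linspace(t_hi / 50.0, t_hi, 64)
        ld = log_dens(probe)
        peak = np.max(ld)
        if ld[-1] < peak - 34.5 and np.argmax(ld) < len(ld) - 2:
            break
        t_hi *= 2.0
    else:  # pragma: no cover - pathological rate functions
        raise RuntimeError("could not bracket the age distribution")
    grid = np.linspace(t_hi / grid_points, t_hi, grid_points)
    ld = log_dens(grid)
    dens = np.exp(ld - np.max(ld))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(rng.random(size), cdf, np.concatenate([[grid[0]], grid[1:]]))


# ---------------------------------------------------------------------------
# public API


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: model, conditioning, sampling scheme, replicates."""

    model: RateModel
    conditioning: str  # "age" or "taxa"
    value: float  # the age T, or the tip count n
    scheme: SamplingScheme = SamplingScheme("complete")
    replicates: int = 1
    seed: Optional[int] = None
    survival_conditioning: bool = True
    topology: bool = False

    def __post_init__(self):
        if self.conditioning not in ("age", "taxa"):
            raise ValueError("conditioning must be 'age' or 'taxa'")
        if self.replicates < 1:
            raise ValueError("replicates >= 1 required")
        if self.conditioning == "age" and not self.value > 0:
            raise ValueError("age conditioning requires T > 0")
        if self.conditioning == "taxa" and self.value < 2:
            raise ValueError("taxa conditioning requires n >= 2")
        if not self.survival_conditioning:
            raise ValueError(
                "a reconstructed tree rooted at the MRCA only exists when both "
                "root lineages survive; unconditioned likelihoods are available "
                "via condition_on_survival=False in bdiv.likelihood instead"
            )


def simulate_reconstructed(
    spec: SimulationSpec, rng: Optional[np.random.Generator] = None
) -> List[ReconstructedTree]:
    """Simulate reconstructed trees, applying the requested sampling scheme."""
    if rng is None:
        if spec.seed is None:
            raise ValueError("provide a seed (or an explicit Generator) for reproducibility")
        rng = np.random.default_rng(spec.seed)
    model, scheme = spec.model, spec.scheme

    trees: List[ReconstructedTree] = []
    if spec.conditioning == "age":
        # fixed MRCA age: geometric subtree sizes, i.i.d. divergence times,
        # then the literal sampling scheme is applied to the complete tree
        T = float(spec.value)
        need_topology = spec.topology or scheme.kind == "uniform"
        counts = _draw_total_tips(model, T, rng, spec.replicates)
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T))
        for rep in range(spec.replicates):
            n = int(counts[rep])
            extra = np.sort(dist.rvs(n - 2, rng)) if n > 2 else np.empty(0)
            times = np.concatenate([[0.0], extra])
            topo = _assemble_topology(times, T, rng) if need_topology else None
            tree = ReconstructedTree(times, T, n=n, topology=topo)
            if scheme.kind == "uniform":
                tree = apply_uniform_sampling(tree, scheme.rho, rng=rng)
            elif scheme.kind == "diversified":
                m = max(2, int(round(scheme.rho * n)))
                tree = apply_diversified_sampling(tree, m)
            trees.append(tree)
        return trees

    # taxa conditioning: ``value`` is the number of *sampled* tips; the MRCA
    # age is drawn from its induced distribution and the sampled tree is
    # generated directly in its i.i.d. divergence-time representation
    m_obs = int(spec.value)
    if scheme.kind == "uniform":
        # the rho-thinned reconstructed process is itself a birth-death
        # sampling law with the rho-modified q, so the sampled tree can be
        # simulated directly (conditioned on the sampled MRCA age)
        ages = draw_age_given_taxa(model, m_obs, spec.replicates, rng, rho=scheme.rho)
        n_total = max(m_obs, int(round(m_obs / scheme.rho)))
        for rep in range(spec.replicates):
            T = float(ages[rep])
            dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T), rho=scheme.rho)
            extra = np.sort(dist.rvs(m_obs - 2, rng)) if m_obs > 2 else np.empty(0)
            times = np.concatenate([[0.0], extra])
            topo = _assemble_topology(times, T, rng) if spec.topology else None
            trees.append(ReconstructedTree(times, T, n=n_total, topology=topo))
        return trees

    n_total = m_obs if scheme.kind == "complete" else max(
        m_obs, int(round(m_obs / scheme.rho))
    )
    ages = draw_age_given_taxa(model, n_total, spec.replicates, rng, rho=1.0)
    for rep in range(spec.replicates):
        T = float(ages[rep])
        dist = SpeciationTimeDistribution(ProcessWindow(model, 0.0, T))
        extra = np.sort(dist.rvs(n_total - 2, rng)) if n_total > 2 else np.empty(0)
        times = np.concatenate([[0.0], extra])
        topo = _assemble_topology(times, T, rng) if spec.topology else None
        tree = ReconstructedTree(times, T, n=n_total, topology=topo)
        if scheme.kind == "diversified":
            tree = apply_diversified_sampling(tree, m_obs)
        trees.append(tree)
    return trees


def apply_diversified_sampling(tree: ReconstructedTree, m: int) -> ReconstructedTree:
    """Keep only the tips descending from the m-1 oldest speciation events.

    Removing the tips created by the n - m most recent speciation events
    (keeping one descendant per removed event) leaves exactly the m - 1
    oldest divergence times; the MRCA and age are unchanged.
    """
    n = tree.m
    if m > n:
        raise ValueError(f"cannot keep m={m} tips of a tree with {n}")
    if m < 2:
        raise ValueError("diversified sampling must keep at least 2 tips")
    if m == n:
        return tree
    times = tree.divergence_times[:m - 1]
    return ReconstructedTree(times.copy(), tree.age, n=tree.n)


def apply_uniform_sampling(
    tree: ReconstructedTree,
    rho: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_rejections: int = 10000,
    return_rejections: bool = False,
):
    """Retain each tip independently with probability rho and prune.

    If fewer than two tips survive the draw is rejected and redrawn; the
    rejection count is available via ``return_rejections=True``.  The
    pruned tree is re-rooted at the MRCA of the retained tips, so its age
    can be younger than the original age.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"rho={rho} outside (0, 1]")
    if rho == 1.0:
        return (tree, 0) if return_rejections else tree
    if tree.topology is None:
        raise ValueError("uniform thinning needs a topology; simulate with topology=True")
    if rng is None:
        rng = np.random.default_rng(seed)

    rejections = 0
    while True:
        keep = rng.random(tree.m) < rho
        if keep.sum() >= 2:
            break
        rejections += 1
        if rejections > max_rejections:
            raise RuntimeError("uniform sampling kept < 2 tips in every redraw")
    keep_ids = set(np.flatnonzero(keep).tolist())

    def prune(node: _Node):
        """Return (surviving subtree root or None); unary nodes suppressed."""
        if node.is_tip:
            return node if node.tip_id in keep_ids else None
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        return node

    import copy

    new_root = prune(copy.deepcopy(tree.topology))
    # the sampled MRCA is the first node (from the root) with >= 2 children
    t_mrca = new_root.time if not new_root.is_tip else tree.age

    times, order = [], []

    def collect(node: _Node):
        if node.is_tip:
            return
        times.append(node.time - t_mrca)
        for c in node.children:
            collect(c)

    collect(new_root)
    new_age = tree.age - t_mrca
    # re-zero tip ids and node times relative to the new MRCA
    def shift(node: _Node):
        node.time -= t_mrca
        for c in node.children:
            shift(c)

    shift(new_root)
    out = ReconstructedTree(np.sort(np.asarray(times)), new_age, n=tree.n,
                            topology=new_root)
    return (out, rejections) if return_rejections else out
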
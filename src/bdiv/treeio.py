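"""Reading and validating ultrametric Newick trees.

Parsing is delegated to dendropy; this layer enforces the modelling
contract -- rooted, strictly bifurcating, ultrametric chronograms with
branch lengths -- and converts node depths into the divergence-time
representation used by the likelihoods (times measured forward from the
MRCA).  Time units are whatever the tree uses; rates come back in inverse
units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import dendropy
import numpy as np

from .likelihood import ReconstructedTree, SamplingScheme

__all__ = ["TreeRecord", "read_newick", "to_reconstructed", "write_newick",
           "load_config"]

#: relative (to tree height) tolerance for ultrametricity
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class TreeRecord:
    newick_source: str
    tip_labels: List[str]
    node_ages: Dict[str, float]  # internal-node key -> age (time before present)
    age: float  # root age = tree height
    divergence_depths: np.ndarray  # internal-node depths since the root, sorted
    is_ultrametric: bool
    tree: dendropy.Tree = field(repr=False, default=None)

    @property
    def m(self) -> int:
        return len(self.tip_labels)


def read_newick(
    source: Union[str, os.PathLike],
    ultrametric_rtol: float = ULTRAMETRIC_RTOL,
    repair: bool = False,
) -> TreeRecord:
    """Parse a Newick chronogram into a validated :class:`TreeRecord`.

    ``source`` may be a path or a literal Newick string.  Unrooted or
    multifurcating trees, missing branch lengths, and deviations from
    ultrametricity beyond ``ultrametric_rtol`` (relative to tree height)
    are rejected with specific diagnostics.  With ``repair=True``,
    sub-tolerance tip-depth deviations are snapped to the mean height
    instead of merely tolerated; the repair is never silent (it is opt-in).
    """
    text = str(source)
    if "(" not in text or ";" not in text:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as err:  # dendropy raises assorted parse errors
        raise ValueError(f"could not parse Newick input: {err}") from None

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has branches without lengths; a chronogram is required")

    for node in tree.preorder_node_iter():
        nc = len(node.child_nodes())
        if nc == 0:
            continue
        if nc != 2:
            where = "root" if node is tree.seed_node else "internal node"
            raise ValueError(
                f"{where} with {nc} children: only rooted, strictly bifurcating "
                "trees are supported (resolve polytomies / root the tree first)"
            )

    # depths from the root
    depth: Dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + float(node.edge.length)

    tip_nodes = [n for n in tree.leaf_node_iter()]
    tip_depths = np.array([depth[n] for n in tip_nodes])
    height = float(np.mean(tip_depths))
    if height <= 0:
        raise ValueError("tree height must be positive")
    dev = np.max(np.abs(tip_depths - height))
    ultrametric = dev <= ultrametric_rtol * height
    if not ultrametric:
        raise ValueError(
            f"tree is not ultrametric: max root-to-tip deviation {dev:.3g} exceeds "
            f"{ultrametric_rtol:.1g} x height ({height:.6g}); pass repair=True only "
            "for sub-tolerance rounding noise"
        )
    if repair:
        for n in tip_nodes:
            depth[n] = height

    internal_depths = np.sort(
        [depth[n] for n in tree.preorder_node_iter() if n.child_nodes()]
    )
    node_ages = {
        f"node{i}": height - d for i, d in enumerate(internal_depths)
    }
    labels = [t.taxon.label if t.taxon else f"tip{i}" for i, t in enumerate(tip_nodes)]
    return TreeRecord(
        newick_source=text.strip(),
        tip_labels=labels,
        node_ages=node_ages,
        age=height,
        divergence_depths=np.asarray(internal_depths, dtype=float),
        is_ultrametric=True,
        tree=tree,
    )


def to_reconstructed(
    record: TreeRecord,
    scheme: Optional[SamplingScheme] = None,
    total_species: Optional[int] = None,
) -> ReconstructedTree:
    """Convert a parsed chronogram to the likelihoods' time-since-MRCA form.

    ``total_species`` is the known number of extant species in the clade
    (sampled plus missing); when omitted it is taken from the scheme's
    sampling fraction as round(m / rho).
    """
    m = record.m
    if total_species is None:
        rho = scheme.rho if scheme is not None else 1.0
        total_species = int(round(m / rho))
    if total_species < m:
        raise ValueError(f"total_species={total_species} < number of tips {m}")
    times = record.divergence_depths - record.divergence_depths[0]
    return ReconstructedTree(times, age=float(record.age), n=total_species)


def load_config(path) -> dict:
    """Read a YAML analysis configuration.

    Recognized keys (all optional): ``model`` (e.g. "M4"), ``params``
    (list, in the registry's documented order), ``scheme``
    (complete/uniform/diversified), ``rho``, ``total_species``,
    ``criterion`` (AICc/BIC), ``restarts``, ``seed``.
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping of option: value")
    return cfg


def write_newick(record_or_text, path) -> None:
    text = record_or_text.newick_source if isinstance(record_or_text, TreeRecord) \
        else str(record_or_text)
    with open(path, "w") as fh:
        fh.write(text.rstrip() + "\n")
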
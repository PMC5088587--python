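"""Distance-based phylogenetics: p/Poisson distances, Neighbor-Joining,
bootstrap supports and clade labeling.

The tree builder is standard NJ (Q-matrix selection criterion with
Studier-Keppler distance updates), which recovers additive distance
matrices exactly.  Joins are tie-broken by the smallest (i, j) index pair
and negative branch lengths are clamped to zero, so trees are deterministic
functions of the input matrix.  Trees are returned as scikit-bio
``TreeNode`` objects with a trifurcating root (the unrooted NJ convention);
bootstrap supports are the percentage of column-resampled replicate trees
containing each internal bipartition of the full-data tree, written as
internal node labels in Newick output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .sequence_io import SequenceRecord

DISTANCE_MODELS = ("p_distance", "poisson")


@dataclass
class MultipleAlignment:
    """An aligned set of equal-length gapped sequences."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment ids must be unique")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "MultipleAlignment":
        if not records:
            raise ValueError("no records")
        return cls([r.id for r in records], [r.residues for r in records],
                   records[0].alphabet)

    def to_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.rows).encode(), dtype="S1"
        ).reshape(self.n_rows, self.n_cols)

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        """Bootstrap replicate: columns resampled with replacement."""
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        arr = self.to_array()[:, cols]
        return MultipleAlignment(
            list(self.ids), [row.tobytes().decode() for row in arr], self.alphabet
        )


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    saturated: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if (d < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.isfinite(d).all():
            raise ValueError("distance matrix has non-finite entries")
        np.fill_diagonal(d, 0.0)
        self.d = d


GAP = ord("-")


def pairwise_distance(msa: MultipleAlignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise p-distance or Poisson-corrected distance.

    Gap-containing columns are deleted pairwise: p = mismatches / compared
    columns over the columns where both rows have residues.  The Poisson
    correction is d = -ln(1 - p); pairs at or beyond saturation (p such that
    the log is undefined) are clamped to the largest resolvable distance for
    the number of compared columns and flagged in ``saturated``.
    """
    if model not in DISTANCE_MODELS:
        raise ValueError(f"unknown distance model {model!r}")
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arr = msa.to_array().view(np.uint8)
    n = msa.n_rows
    ok = arr != GAP
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns for pair ({msa.ids[i]}, {msa.ids[j]})"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / compared
            if model == "p_distance":
                dist = p
            else:
                if p >= 1.0 - 1e-12:
                    p = 1.0 - 1.0 / (2.0 * compared)
                    saturated.append((msa.ids[i], msa.ids[j]))
                dist = -math.log1p(-p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(msa.ids), d, saturated)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-Joining tree from a distance matrix (n >= 3).

    Exact on additive matrices; negative branch lengths are clamped to 0.
    Returns an unrooted tree as a ``TreeNode`` with a trifurcating root,
    2n-3 edges in total.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # row-major: smallest (i, j)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(0.0, float(li))
        child_j.length = max(0.0, float(lj))
        new = TreeNode(children=[child_i, child_j])
        # Studier-Keppler update
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final three nodes around a trifurcating root
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip((a, b, c), (la, lb, lc)):
        node.length = max(0.0, float(length))
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode, ref_leaf: str) -> dict[frozenset[str], TreeNode]:
    """Internal-edge bipartitions, each canonicalized as the side not
    containing ``ref_leaf``."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    bips: dict[frozenset[str], TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if ref_leaf in side:
            side = all_leaves - side
        bips[side] = node
    return bips


def bootstrap_support(
    msa: MultipleAlignment,
    model: str = "p_distance",
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float], int]:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the full-data tree is the percentage of
    replicate trees containing the same bipartition.  Replicates in which
    some pair has no comparable columns are redrawn (the count of redraws is
    returned).  Supports are attached as internal node names (integer
    percentages) for Newick output.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    full_tree = neighbor_joining(pairwise_distance(msa, model))
    ref = msa.ids[0]
    bips = _bipartitions(full_tree, ref)
    hits = {bip: 0 for bip in bips}
    rng = np.random.default_rng(seed)
    redraws = 0
    done = 0
    while done < n_replicates:
        rep = msa.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep, model))
        except ValueError:
            redraws += 1
            if redraws > 100 * n_replicates:
                raise RuntimeError("too many unusable bootstrap replicates")
            continue
        rep_bips = set(_bipartitions(rep_tree, ref))
        for bip in hits:
            if bip in rep_bips:
                hits[bip] += 1
        done += 1
    supports = {bip: 100.0 * k / n_replicates for bip, k in hits.items()}
    for bip, node in bips.items():
        node.name = str(int(round(supports[bip])))
    return full_tree, supports, redraws


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


@dataclass
class GroupLabel:
    """The smallest clade (bipartition side) containing a set of seed
    leaves."""

    leaves: frozenset[str]
    spans_root: bool  # seeds straddle every bipartition: whole leaf set returned
    absent_genomes: frozenset[str]  # genomes with no leaf inside the clade


def label_groups(
    tree: TreeNode,
    leaf_to_genome: Mapping[str, str],
    seed_leaves: Sequence[str],
) -> GroupLabel:
    """Find the smallest clade containing the seed leaves and report its
    composition, flagging genomes absent from it (e.g. a monocot-specific
    group has zero eudicot leaves)."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    seeds = frozenset(seed_leaves)
    missing = seeds - all_leaves
    if missing:
        raise ValueError(f"seed leaves not in tree: {sorted(missing)}")
    unmapped = all_leaves - set(leaf_to_genome)
    if unmapped:
        raise ValueError(f"tree leaves without genome mapping: {sorted(unmapped)}")
    sides: list[frozenset[str]] = []
    for node in tree.traverse(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        sides.append(side)
        sides.append(all_leaves - side)
    candidates = [s for s in sides if seeds <= s and len(s) < len(all_leaves)]
    if candidates:
        clade = min(candidates, key=lambda s: (len(s), sorted(s)))
        spans_root = False
    else:
        clade = all_leaves
        spans_root = True
    genomes_present = {leaf_to_genome[leaf] for leaf in clade}
    absent = frozenset(set(leaf_to_genome.values()) - genomes_present)
    return GroupLabel(frozenset(clade), spans_root, absent)


def path_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data
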
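"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap.

Alignments are consumed, never built, here.  Distances are uncorrected
p-distances with pairwise gap deletion (a Poisson correction is available
behind a flag).  Neighbor joining follows the Saitou-Nei Q-criterion
agglomeration; negative branch-length estimates are clamped to zero with a
logged warning.  Bootstrap support for an internal edge is the percentage
of column-resampled replicate trees containing the same leaf bipartition.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO
from skbio import DistanceMatrix, TreeNode

log = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "PhyloTree",
    "p_distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "bipartitions",
]

_GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped amino-acid sequences with unique ids."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows differ in length")
        if len(self.rows) != len(self.ids):
            raise ValueError("ids and rows differ in number")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def read(cls, path, fmt: str = "fasta") -> "Alignment":
        """Read an aligned FASTA ('fasta') or Clustal ('clustal') file."""
        aln = AlignIO.read(path, fmt)
        return cls(ids=tuple(r.id for r in aln),
                   rows=tuple(str(r.seq).upper() for r in aln))

    def take_columns(self, idx: np.ndarray) -> "Alignment":
        rows = tuple("".join(r[j] for j in idx) for r in self.rows)
        return Alignment(self.ids, rows)


class PhyloTree:
    """Unrooted weighted tree with optional per-edge bootstrap supports.

    Thin wrapper over an ``skbio.TreeNode`` whose root is the standard
    trifurcating representation of an unrooted tree.  Internal node names
    hold bootstrap supports (percent) when present.
    """

    def __init__(self, root: TreeNode):
        self.root = root

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(t.name for t in self.root.tips())

    def to_newick(self) -> str:
        buf = _io.StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return cls(TreeNode.read(_io.StringIO(text)))

    def supports(self) -> dict[tuple, float]:
        """Canonical bipartition -> support (percent) for labelled edges."""
        out = {}
        for node in self.root.non_tips(include_self=False):
            if node.name is not None:
                out[_canonical_split(node, self.leaf_names)] = float(node.name)
        return out

    def tip_distances(self) -> DistanceMatrix:
        return self.root.tip_tip_distances()


def p_distance_matrix(alignment: Alignment, deletion: str = "pairwise",
                      poisson: bool = False) -> DistanceMatrix:
    """Proportion of differing residues per pair, gaps removed pairwise.

    With ``poisson`` the distance is -ln(1 - p).  A pair with no mutually
    ungapped column is an error naming the pair.
    """
    if deletion != "pairwise":
        raise ValueError("only pairwise deletion is implemented")
    rows = np.array([list(r) for r in alignment.rows])
    ungapped = rows != _GAP
    n = len(alignment.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}")
            p = float((rows[i, both] != rows[j, both]).sum()) / m
            if poisson:
                if p >= 1.0:
                    raise ValueError("p-distance of 1 cannot be Poisson corrected")
                p = -np.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=list(alignment.ids))


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Deterministic: the minimal-Q pair with the smallest (i, j) indices is
    joined at each step.  Negative branch-length estimates are clamped to
    zero (logged).  For an additive input matrix the tree's path lengths
    reproduce the input exactly up to floating-point error.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li)
        b.length = clamp(lj)
        parent.extend([a, b])
        new_d = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  new_d[keep][:, None]]),
                       np.hstack([new_d[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]

    # three-point formulas for the final star join
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [0.5 * (d01 + d02 - d12),
               0.5 * (d01 + d12 - d02),
               0.5 * (d02 + d12 - d01)]
    root = TreeNode()
    for node, L in zip(nodes, lengths):
        node.length = clamp(L)
        root.append(node)
    return PhyloTree(root)


def _canonical_split(node: TreeNode, all_leaves: frozenset) -> tuple:
    """Canonical orientation of a node's bipartition: the lexicographically
    smaller sorted side."""
    side = tuple(sorted(t.name for t in node.tips()))
    other = tuple(sorted(all_leaves - set(side)))
    return min(side, other)


def bipartitions(tree: PhyloTree) -> set[tuple]:
    """Non-trivial leaf splits, one per internal edge."""
    leaves = tree.leaf_names
    out = set()
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            out.add(_canonical_split(node, leaves))
    return out


def bootstrap_support(alignment: Alignment, n_reps: int, seed: int,
                      poisson: bool = False) -> PhyloTree:
    """NJ tree from the full alignment, internal edges labelled with the
    percentage of column-resampled replicates containing the same split.

    With fewer than 4 leaves there are no internal edges and the tree is
    returned without supports.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = neighbor_joining(p_distance_matrix(alignment, poisson=poisson))
    if len(alignment.ids) < 4:
        return tree
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    counts: dict[tuple, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = neighbor_joining(
            p_distance_matrix(alignment.take_columns(idx), poisson=poisson))
        for split in bipartitions(rep):
            counts[split] = counts.get(split, 0) + 1
    leaves = tree.leaf_names
    for node in tree.root.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            split = _canonical_split(node, leaves)
            node.name = str(round(100.0 * counts.get(split, 0) / n_reps, 6))
    return tree
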
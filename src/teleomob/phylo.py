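"""Distance-based phylogenetics over conserved protein domains.

Uncorrected amino-acid p-distances (pairwise or complete gap deletion),
neighbor-joining tree construction (Saitou-Nei Q criterion, with
clamp-and-transfer handling of negative branch lengths), and bootstrap
support by column resampling.  Trees serialize as Newick with support
percentages as internal node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import SequenceRecord

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "PhyloParams",
    "TreeNode",
    "p_distance",
    "nj_tree",
    "bootstrap_support",
    "tree_splits",
]

_GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class MultipleAlignment:
    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon ids")
        if self.rows:
            n = len(self.rows[0])
            if any(len(r) != n for r in self.rows):
                raise ValueError("alignment rows differ in length")

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "MultipleAlignment":
        records = list(records)
        return cls(tuple(r.id for r in records), tuple(r.seq.upper() for r in records))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        mat = np.array([list(r) for r in self.rows])
        return MultipleAlignment(
            self.taxa, tuple("".join(row) for row in mat[:, cols])
        )


@dataclass
class DistanceMatrix:
    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")


@dataclass(frozen=True)
class PhyloParams:
    bootstrap_replicates: int = 1000
    seed: int = 0
    distance: str = "p_distance"
    gap_handling: str = "pairwise_deletion"  # or "complete_deletion"

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; the NJ result is rooted at a
    trifurcation.  ``label`` carries bootstrap support on internal nodes."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    label: str | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._newick_inner() for c in self.children)
        lab = self.label or ""
        return f"({inner}){lab}:{self.length:.6f}"


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def p_distance(
    alignment: MultipleAlignment,
    gap_handling: str = "pairwise_deletion",
) -> DistanceMatrix:
    """Proportion of differing sites per pair of rows.

    Under ``pairwise_deletion`` the columns holding a gap in either row
    of a pair are excluded for that pair; under ``complete_deletion``
    any column with a gap in any row is excluded for all pairs.  A pair
    left with zero comparable columns raises ``ValueError`` naming it.
    """
    mat = np.array([list(r) for r in alignment.rows])
    gap = np.isin(mat, list(_GAP_CHARS))
    if gap_handling == "complete_deletion":
        keep = ~gap.any(axis=0)
        mat = mat[:, keep]
        gap = gap[:, keep]
    elif gap_handling != "pairwise_deletion":
        raise ValueError(f"unknown gap handling {gap_handling!r}")
    n = len(alignment.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between '{alignment.taxa[i]}' "
                    f"and '{alignment.taxa[j]}'"
                )
            diff = int((mat[i, ok] != mat[j, ok]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(alignment.taxa, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Negative branch lengths clamped to 0; the deficit moves to the
    sister branch so the path length i-j is preserved."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
        li = max(li, 0.0)
    return li, lj


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; exact on additive distances.

    Ties in the Q criterion break deterministically on the
    lexicographically smallest joined taxon-name pair, so the topology
    is invariant to taxon input order.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    # sort key per active node for deterministic tie-breaks
    keys: list[str] = [t for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            ((i, j) for i, j in cand if i < j),
            key=lambda p: tuple(sorted((keys[active[p[0]]], keys[active[p[1]]]))),
        )
        ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2 + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = (sub[ai, ak] + sub[aj, ak] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    nodes[i].length = max(0.0, (dij + dik - djk) / 2)
    nodes[j].length = max(0.0, (dij + djk - dik) / 2)
    nodes[k].length = max(0.0, (dik + djk - dij) / 2)
    order = sorted((i, j, k), key=lambda x: keys[x])
    return TreeNode(children=[nodes[x] for x in order])


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Internal (non-trivial) bipartitions, each encoded canonically as
    the side not containing the lexicographically smallest taxon."""
    all_taxa = tree.leaf_names()
    ref = min(all_taxa)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> None:
        for c in node.children:
            side = c.leaf_names()
            if 2 <= len(side) <= len(all_taxa) - 2:
                if ref in side:
                    side = all_taxa - side
                splits.add(frozenset(side))
            walk(c)

    walk(tree)
    return splits


def bootstrap_support(
    alignment: MultipleAlignment,
    params: PhyloParams | None = None,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree of the full alignment with per-split bootstrap support.

    Columns are resampled with replacement ``bootstrap_replicates``
    times; each replicate tree is rebuilt with the same distance and NJ
    settings, and a split's support is the percentage of replicate trees
    containing it.  Supports are written onto the internal node labels
    of the returned tree.
    """
    params = params or PhyloParams()
    full = nj_tree(p_distance(alignment, params.gap_handling))
    target = tree_splits(full)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(params.seed)
    for _ in range(params.bootstrap_replicates):
        rep = alignment.resample_columns(rng)
        rep_tree = nj_tree(p_distance(rep, params.gap_handling))
        rep_splits = tree_splits(rep_tree)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / params.bootstrap_replicates for s, c in counts.items()}

    all_taxa = full.leaf_names()
    ref = min(all_taxa)

    def annotate(node: TreeNode) -> None:
        for c in node.children:
            if not c.is_leaf():
                side = c.leaf_names()
                key = frozenset(all_taxa - side) if ref in side else frozenset(side)
                if key in support:
                    c.label = f"{support[key]:.0f}"
            annotate(c)

    annotate(full)
    return full, support
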
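"""Poisson-corrected protein distances, neighbor-joining, and bootstrap
bipartition supports.

The tree is built with the Saitou-Nei neighbor-joining algorithm on
Poisson-corrected distances computed with pairwise deletion (columns
gapped in either of the two sequences are ignored). Supports come from
resampling alignment columns with replacement and counting, for every
internal bipartition of the full-data tree, the percentage of replicate
trees that contain it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import SeqRecord

__all__ = [
    "MultipleAlignment", "DistanceMatrix", "Tree", "TreeNode",
    "poisson_distance", "distance_matrix", "nj_tree",
    "bootstrap_supports", "write_newick",
]


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least two rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_records(cls, records: list[SeqRecord]) -> "MultipleAlignment":
        return cls([r.id for r in records], [r.sequence for r in records])


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with a "
                             "zero diagonal")
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("distances must be finite and non-negative")
        self.values = v


class SaturationError(ValueError):
    """Distance undefined: all compared sites differ, or nothing compared."""


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance -ln(1-p) with pairwise deletion."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    compared = mismatch = 0
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise SaturationError("no columns compared under pairwise deletion")
    p = mismatch / compared
    if p >= 1.0:
        raise SaturationError("all compared sites differ (p >= 1)")
    return -math.log1p(-p)


def _encode(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer("".join(aln.rows).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(len(aln.rows), aln.n_columns)
    gap = arr == ord("-")
    return arr, gap


def _pair_distance_arrays(aln: MultipleAlignment
                          ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per-pair boolean column arrays: compared (both ungapped) and
    mismatching-and-compared."""
    arr, gap = _encode(aln)
    n = len(aln.ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    comp = np.empty((len(pairs), aln.n_columns), dtype=np.float32)
    mism = np.empty_like(comp)
    for k, (i, j) in enumerate(pairs):
        both = ~(gap[i] | gap[j])
        comp[k] = both
        mism[k] = both & (arr[i] != arr[j])
    return comp, mism, pairs


def distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    comp, mism, pairs = _pair_distance_arrays(aln)
    n = len(aln.ids)
    d = np.zeros((n, n))
    c = comp.sum(axis=1)
    m = mism.sum(axis=1)
    for k, (i, j) in enumerate(pairs):
        if c[k] == 0:
            raise SaturationError(
                f"no compared columns between {aln.ids[i]} and {aln.ids[j]}")
        p = m[k] / c[k]
        if p >= 1.0:
            raise SaturationError(
                f"saturated distance between {aln.ids[i]} and {aln.ids[j]}")
        d[i, j] = d[j, i] = -math.log1p(-p)
    return DistanceMatrix(aln.ids, d)


@dataclass
class TreeNode:
    name: str | None = None
    branch_length: float | None = None
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Unrooted phylogeny stored with a trifurcating origin node."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            if node.is_leaf():
                out.append(node)
            for ch in node.children:
                walk(ch)
        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, each keyed by the canonical side
        (the side NOT containing the alphabetically first leaf)."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if node is not self.root and len(below) > 1 and \
                    len(all_leaves - below) > 1:
                key = below if ref not in below else all_leaves - below
                out[key] = node
            return below

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch (the MEGA-compatible convention), preserving the
    length of the path through the new node. Ties in Q are broken by the
    smallest (i, j) index pair so the result is deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        k = int(np.argmin(q))
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].branch_length = li
        nodes[j].branch_length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d[i, :] = new_d
        d[:, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        nodes[idx].branch_length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root)


def _bootstrap_matrices(comp: np.ndarray, mism: np.ndarray,
                        weights: np.ndarray, ids: list[str]
                        ) -> DistanceMatrix | None:
    c = comp @ weights
    m = mism @ weights
    if (c == 0).any():
        return None
    p = m / c
    # saturated pairs in a replicate: cap p just below 1 so the replicate
    # still yields a (very long) branch instead of being discarded
    np.clip(p, 0.0, 1.0 - 1.0 / (2.0 * c.max()), out=p)
    n = len(ids)
    d = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = -math.log1p(-p[k])
            k += 1
    return DistanceMatrix(ids, d)


def bootstrap_supports(aln: MultipleAlignment, n_reps: int = 1000,
                       seed: int = 0) -> Tree:
    """NJ tree from the full alignment, with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal bipartition of the full-data tree is the percentage
    of replicate trees containing it. Deterministic given ``seed``.
    """
    if len(aln.ids) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    tree = nj_tree(distance_matrix(aln))
    if n_reps <= 0:
        return tree
    comp, mism, _ = _pair_distance_arrays(aln)
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    counts: dict[frozenset, int] = {key: 0 for key in tree.bipartitions()}
    used = 0
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        weights = np.bincount(idx, minlength=ncol).astype(np.float32)
        dm = _bootstrap_matrices(comp, mism, weights, aln.ids)
        if dm is None:
            continue
        used += 1
        rep_bips = nj_tree(dm).bipartitions().keys()
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    if used:
        for key, node in tree.bipartitions().items():
            node.support = int(round(100.0 * counts[key] / used))
    return tree


_NEWICK_UNSAFE = set(" ()[]{}:;,'\"")


def _quote(name: str) -> str:
    if any(ch in _NEWICK_UNSAFE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf():
        label = _quote(node.name or "")
    else:
        label = "" if node.support is None else str(int(node.support))
        label = f"({','.join(_newick_node(ch) for ch in node.children)}){label}"
    if node.branch_length is not None:
        label += f":{node.branch_length:.6f}"
    return label


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick: branch lengths to 6 decimals, integer
    bootstrap labels on internal nodes, unsafe leaf names quoted."""
    if len(tree.leaves()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    return f"({','.join(_newick_node(ch) for ch in tree.root.children)});" \
        if tree.root.branch_length is None and tree.root.name is None \
        else _newick_node(tree.root) + ";"
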
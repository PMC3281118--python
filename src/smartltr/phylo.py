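"""Pairwise distances between element sequences and neighbor-joining trees.

Distances come from all-pairs global alignment (gap columns excluded) under
a p-distance or Jukes-Cantor model; the tree is built with the Saitou-Nei
neighbor-joining algorithm and emitted as newick with branch lengths.
NJ is consistent on additive matrices: if the input distances fit a tree
exactly, that tree (topology and branch lengths) is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import global_divergence_counts
from .dating import JC_SATURATION_P, jukes_cantor

SATURATION_CEILING = 2.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _pair_distance(a: str, b: str, model: str) -> tuple[float, bool]:
    sites, mm = global_divergence_counts(a, b)
    p = mm / sites if sites else 0.0
    if model == "p_distance":
        return p, False
    if p >= JC_SATURATION_P:
        return SATURATION_CEILING, True
    return jukes_cantor(p), False


def pairwise_distances(
    seqs: list[tuple[str, str]], model: str = "p_distance"
) -> DistanceMatrix:
    """All-pairs aligned distances between labelled sequences.

    Saturated Jukes-Cantor pairs are set to the ceiling (2.0) and flagged.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if model not in ("p_distance", "jukes_cantor"):
        raise ValueError(f"unknown model {model!r}")
    labels = [l for l, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    n = len(seqs)
    m = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            d, sat = _pair_distance(seqs[i][1], seqs[j][1], model)
            m[i, j] = m[j, i] = d
            if sat:
                saturated.append((labels[i], labels[j]))
    return DistanceMatrix(labels, m, saturated_pairs=saturated)


def distances_from_alignment(
    aligned: list[tuple[str, str]], model: str = "p_distance"
) -> DistanceMatrix:
    """Distances from pre-aligned (equal-length) sequences; gap columns of
    each pair are excluded pairwise. Used by the bootstrap."""
    if len({len(s) for _, s in aligned}) != 1:
        raise ValueError("aligned sequences must have equal length")
    labels = [l for l, _ in aligned]
    n = len(aligned)
    m = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[i][1], aligned[j][1]
            sites = mm = 0
            for x, y in zip(a, b):
                if x == "-" or y == "-":
                    continue
                sites += 1
                mm += x != y
            p = mm / sites if sites else 0.0
            if model == "jukes_cantor":
                if p >= JC_SATURATION_P:
                    d, sat = SATURATION_CEILING, True
                else:
                    d, sat = jukes_cantor(p), False
            else:
                d, sat = p, False
            m[i, j] = m[j, i] = d
            if sat:
                saturated.append((labels[i], labels[j]))
    return DistanceMatrix(labels, m, saturated_pairs=saturated)


# -- neighbor joining -------------------------------------------------------

class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (node, branch_length)

    def leaves(self) -> frozenset:
        if self.label is not None:
            return frozenset([self.label])
        out = set()
        for ch, _ in self.children:
            out |= ch.leaves()
        return frozenset(out)

    def newick(self) -> str:
        if self.label is not None:
            return self.label
        inner = ",".join(f"{ch.newick()}:{bl:.10g}" for ch, bl in self.children)
        return f"({inner})"


def _nj_tree(labels: list[str], matrix: np.ndarray) -> _Node:
    nodes = [_Node(label=l) for l in labels]
    # each cluster keyed by its lexicographically smallest leaf label for ties
    keys = list(labels)
    d = matrix.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 3:
        n = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (n - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie)
                if best is None or cand < best[0:2]:
                    best = (q, tie, i, j)
        _, _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        bj = d[i, j] - bi
        bi, bj = _clamp_pair(bi, bj)
        parent = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        new = len(nodes) - 1
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new]
    if len(active) == 3:
        i, j, k = active
        bi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        bj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        bk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        bi, bj, bk = (max(0.0, b) for b in (bi, bj, bk))
        return _Node(children=[(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)])
    if len(active) == 2:
        i, j = active
        return _Node(children=[(nodes[i], d[i, j] / 2), (nodes[j], d[i, j] / 2)])
    return nodes[active[0]]


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, moving the deficit to its sister."""
    if bi < 0:
        bj += bi
        bi = 0.0
        bj = max(bj, 0.0)
    elif bj < 0:
        bi += bj
        bj = 0.0
        bi = max(bi, 0.0)
    return bi, bj


def neighbor_joining(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf). Negative
    branch lengths are clamped to zero with the deficit moved to the sister
    branch.
    """
    if len(d.labels) < 3:
        raise ValueError("need at least 3 taxa")
    tree = _nj_tree(d.labels, d.matrix)
    return tree.newick() + ";"


def tree_distances(d: DistanceMatrix) -> np.ndarray:
    """Leaf-to-leaf path lengths of the NJ tree, in input label order."""
    tree = _nj_tree(d.labels, d.matrix)
    idx = {l: i for i, l in enumerate(d.labels)}
    n = len(d.labels)
    out = np.zeros((n, n))

    def walk(node, depths):
        if node.label is not None:
            return {node.label: 0.0}
        below = {}
        child_maps = []
        for ch, bl in node.children:
            cm = walk(ch, depths)
            cm = {l: x + bl for l, x in cm.items()}
            child_maps.append(cm)
        for a_i, cm_a in enumerate(child_maps):
            for cm_b in child_maps[a_i + 1 :]:
                for la, xa in cm_a.items():
                    for lb, xb in cm_b.items():
                        out[idx[la], idx[lb]] = out[idx[lb], idx[la]] = xa + xb
            below.update(cm_a)
        below.update(child_maps[-1])
        return below

    walk(tree, 0.0)
    return out


def _bipartitions(node: _Node, all_leaves: frozenset) -> set[frozenset]:
    parts = set()

    def walk(nd):
        if nd.label is not None:
            return
        for ch, _ in nd.children:
            ls = ch.leaves()
            if 1 < len(ls) < len(all_leaves) - 1:
                parts.add(min(ls, frozenset(all_leaves - ls), key=sorted))
            walk(ch)

    walk(node)
    return parts


def bootstrap_support(
    aligned: list[tuple[str, str]],
    n_replicates: int = 100,
    model: str = "p_distance",
    seed: int = 0,
) -> tuple[str, dict[frozenset, float]]:
    """Column-resampling bootstrap on a pre-aligned set of sequences.

    Returns (newick of the full-data NJ tree, support in [0, 100] for each
    internal bipartition of that tree). Requires equal-length input; for
    unaligned elements align them first (the all-pairs route used for
    distances yields no shared column set to resample).
    """
    rng = np.random.default_rng(seed)
    full = distances_from_alignment(aligned, model=model)
    tree = _nj_tree(full.labels, full.matrix)
    all_leaves = tree.leaves()
    target = _bipartitions(tree, all_leaves)
    counts = {bp: 0 for bp in target}
    length = len(aligned[0][1])
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [
            (label, "".join(seq[c] for c in cols)) for label, seq in aligned
        ]
        dm = distances_from_alignment(resampled, model=model)
        rep = _nj_tree(dm.labels, dm.matrix)
        parts = _bipartitions(rep, all_leaves)
        for bp in target:
            if bp in parts:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    return tree.newick() + ";", support
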
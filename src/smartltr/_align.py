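"""Shared pairwise-alignment helpers.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` so every module uses
one global and one local alignment route with explicit scoring, plus a
seed-and-extend scanner for finding *all* local matches of a query in a long
subject (PairwiseAligner alone only returns the single optimal alignment).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def make_aligner(
    mode: str = "global",
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -2,
    gap_extend: float = -2,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # open/extend assignment covers end gaps too (plain Needleman-Wunsch)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def aligned_stats(alignment, a: str, b: str) -> tuple[int, int]:
    """Count (aligned_sites, mismatches) over non-gap columns of an alignment."""
    sites = 0
    mismatches = 0
    for (ta, tb), (qa, qb) in zip(*alignment.aligned):
        sites += tb - ta
        for x, y in zip(a[ta:tb], b[qa:qb]):
            if x != y:
                mismatches += 1
    return sites, mismatches


def global_divergence_counts(
    a: str, b: str, match: float = 1, mismatch: float = -1, gap: float = -2
) -> tuple[int, int]:
    """Globally align two sequences, return (aligned_sites, mismatches).

    Gap columns are excluded from the aligned-site count.
    """
    aligner = make_aligner("global", match, mismatch, gap, gap)
    alignment = aligner.align(a, b)[0]
    return aligned_stats(alignment, a, b)


@dataclass
class LocalHit:
    """One local alignment of a query inside a subject sequence."""

    subject_start: int
    subject_end: int
    query_start: int
    query_end: int
    score: float
    identity: float
    query_blocks: list[tuple[int, int]]  # aligned query intervals


def _cluster_seeds(seeds: list[tuple[int, int]], qlen: int, band: int = 24):
    """Group (subject_pos, query_pos) seeds into diagonal bands."""
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    clusters: list[list[tuple[int, int]]] = []
    for s in seeds:
        placed = False
        for cl in clusters:
            last = cl[-1]
            if abs((s[0] - s[1]) - (last[0] - last[1])) <= band and 0 <= s[0] - last[0] <= qlen:
                cl.append(s)
                placed = True
                break
        if not placed:
            clusters.append([s])
    return clusters


def local_hits(
    subject: str,
    query: str,
    k: int = 11,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
    min_score: float = 0,
    min_len: int = 1,
) -> list[LocalHit]:
    """Find all local alignments of ``query`` in ``subject``.

    Seed with exact ``k``-mers shared between the two sequences, band the
    seeds by diagonal, and run an optimal local alignment of the query
    against each seeded subject window. Hits below ``min_score`` or shorter
    than ``min_len`` subject bases are discarded; overlapping hits keep the
    best-scoring representative.
    """
    qlen = len(query)
    if qlen < k or len(subject) < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(qlen - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    seeds = []
    for j in range(len(subject) - k + 1):
        for qi in index.get(subject[j : j + k], ()):
            seeds.append((j, qi))
    if not seeds:
        return []
    aligner = make_aligner("local", match, mismatch, gap_open, gap_extend)
    hits: list[LocalHit] = []
    for cl in _cluster_seeds(seeds, qlen):
        lo = max(0, min(s[0] - s[1] for s in cl) - 20)
        hi = min(len(subject), max(s[0] + (qlen - s[1]) for s in cl) + 20)
        window = subject[lo:hi]
        alignment = aligner.align(window, query)[0]
        if alignment.score <= 0:
            continue
        tblocks, qblocks = alignment.aligned
        if len(tblocks) == 0:
            continue
        sites, mm = aligned_stats(alignment, window, query)
        if sites == 0:
            continue
        s_start = int(tblocks[0][0]) + lo
        s_end = int(tblocks[-1][1]) + lo
        if s_end - s_start < min_len or alignment.score < min_score:
            continue
        hits.append(
            LocalHit(
                subject_start=s_start,
                subject_end=s_end,
                query_start=int(qblocks[0][0]),
                query_end=int(qblocks[-1][1]),
                score=float(alignment.score),
                identity=(sites - mm) / sites,
                query_blocks=[(int(a), int(b)) for a, b in qblocks],
            )
        )
    # dedupe: overlapping windows can rediscover the same locus
    hits.sort(key=lambda h: (-h.score, h.subject_start))
    kept: list[LocalHit] = []
    for h in hits:
        if all(
            h.subject_end <= o.subject_start or h.subject_start >= o.subject_end
            for o in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.subject_start)
    return kept
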
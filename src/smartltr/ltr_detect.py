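"""De novo structural scan for miniature LTR retrotransposons.

The scan looks for pairs of ungapped direct repeats (the two LTRs) separated
by an internal region, then verifies the hallmarks of an LTR retrotransposon
insertion: 5'TGT...ACA3' termini and a duplicated target site (TSD) on both
flanks.

Candidate search
----------------
A candidate is a triple (offset ``d``, window ``[a, a+L)``) meaning the
repeat copies ``seq[a:a+L]`` and ``seq[a+d:a+d+L]`` with

* ``L >= min_ltr``,
* internal separation ``d - L >= min_internal``,
* total span ``d + L <= max_element``,
* ungapped identity ``matches/L >= min_identity``,

and the window is *maximal*: no valid window on the same offset strictly
contains it. For every offset the per-position equality vector is computed
with numpy, prescreened with a sliding ``min_ltr`` window at threshold
``2*min_identity - 1`` (any valid window must contain such a sub-window, so
the prescreen is complete, not heuristic), and qualifying neighbourhoods are
enumerated exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ElementCall, GenomeRecord

log = logging.getLogger(__name__)


@dataclass
class CandidatePair:
    """A pair of direct repeats that may be the two LTRs of one element."""

    chrom: str
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    repeat_identity: float

    @property
    def internal_span(self) -> tuple[int, int]:
        return self.ltr5_span[1], self.ltr3_span[0]

    @property
    def span(self) -> tuple[int, int]:
        return self.ltr5_span[0], self.ltr3_span[1]

    @property
    def ltr_length(self) -> int:
        return self.ltr5_span[1] - self.ltr5_span[0]

    @property
    def score(self) -> float:
        return self.repeat_identity * self.ltr_length


def find_candidate_pairs(
    genome: GenomeRecord,
    min_ltr: int = 50,
    min_internal: int = 100,
    max_element: int = 2000,
    min_identity: float = 0.80,
    max_n_fraction: float = 0.10,
    resolve_overlaps: bool = True,
) -> list[CandidatePair]:
    """Scan one sequence for direct-repeat pairs (candidate LTR pairs).

    Returns maximal candidates; with ``resolve_overlaps`` overlapping
    candidates are reduced greedily by highest identity x LTR length, ties
    to the leftmost start. Candidates whose span contains more than
    ``max_n_fraction`` N bases are dropped.
    """
    n = genome.length
    if n < 2 * min_ltr + min_internal:
        return []
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    not_n = arr != ord("N")
    is_n = ~not_n
    n_prefix = np.concatenate(([0], np.cumsum(is_n)))
    prescreen_t = max(2 * min_identity - 1, 0.02)
    need = math.ceil(prescreen_t * min_ltr)
    candidates: list[CandidatePair] = []
    d_lo = min_ltr + min_internal
    d_hi = min(max_element - min_ltr, n - min_ltr)
    for d in range(d_lo, d_hi + 1):
        eq = (arr[:-d] == arr[d:]) & not_n[:-d] & not_n[d:]
        m = eq.shape[0]
        if m < min_ltr:
            continue
        csum = np.empty(m + 1, dtype=np.int32)
        csum[0] = 0
        np.cumsum(eq, dtype=np.int32, out=csum[1:])
        wsum = csum[min_ltr:] - csum[:-min_ltr]
        if int(wsum.max(initial=0)) < need:
            continue
        hit_pos = np.nonzero(wsum >= need)[0]
        l_cap = min(d - min_internal, max_element - d)
        windows: list[tuple[int, int, int]] = []
        for seg_lo, seg_hi in _merge_positions(hit_pos, min_ltr):
            lo = max(0, seg_lo - l_cap)
            hi = min(m, seg_hi + min_ltr + l_cap)
            windows.extend(_valid_windows(csum, lo, hi, min_ltr, l_cap, min_identity))
        for a, b, matches in _maximal(windows):
            span_n = n_prefix[a + d + (b - a)] - n_prefix[a]
            if span_n > max_n_fraction * (d + (b - a)):
                continue
            candidates.append(
                CandidatePair(
                    chrom=genome.name,
                    ltr5_span=(a, b),
                    ltr3_span=(a + d, b + d),
                    repeat_identity=matches / (b - a),
                )
            )
    candidates.sort(key=lambda c: (c.span, c.ltr_length))
    if resolve_overlaps:
        candidates = resolve_overlapping(candidates)
    return candidates


def _merge_positions(pos: np.ndarray, gap: int):
    """Merge sorted hit positions closer than ``gap`` into segments."""
    segs = []
    start = prev = int(pos[0])
    for p in pos[1:]:
        p = int(p)
        if p - prev > gap:
            segs.append((start, prev + 1))
            start = p
        prev = p
    segs.append((start, prev + 1))
    return segs


def _valid_windows(csum, lo, hi, min_ltr, l_cap, min_identity):
    """All (a, b, matches) with lo <= a < b <= hi meeting the thresholds."""
    out = []
    max_len = min(l_cap, hi - lo)
    if max_len < min_ltr:
        return out
    lengths = np.arange(min_ltr, max_len + 1)
    for a in range(lo, hi - min_ltr + 1):
        ls = lengths[lengths <= hi - a]
        if ls.size == 0:
            break
        matches = csum[a + ls] - csum[a]
        ok = matches / ls >= min_identity
        for L, mt in zip(ls[ok], matches[ok]):
            out.append((a, a + int(L), int(mt)))
    return out


def _maximal(windows):
    """Keep windows not strictly contained in another valid window."""
    if not windows:
        return []
    windows = sorted(set(windows), key=lambda w: (w[0], -w[1]))
    kept = []
    best_b = -1
    for a, b, mt in windows:
        if b > best_b:
            kept.append((a, b, mt))
            best_b = b
    return kept


def resolve_overlapping(candidates: list[CandidatePair]) -> list[CandidatePair]:
    """Greedy resolution: highest identity x LTR length wins, ties leftmost."""
    order = sorted(candidates, key=lambda c: (-c.score, c.span[0], c.span[1]))
    kept: list[CandidatePair] = []
    occupied: list[tuple[int, int]] = []
    for c in order:
        s, e = c.span
        if all(e <= os or s >= oe for os, oe in occupied):
            kept.append(c)
            occupied.append((s, e))
    kept.sort(key=lambda c: c.span)
    return kept


@dataclass
class ValidationResult:
    calls: list[ElementCall]
    rejected: list[tuple[CandidatePair, str]]


def validate_candidates(
    pairs: list[CandidatePair],
    genome: GenomeRecord,
    tsd_len: int = 5,
    require_motif: bool = True,
    tsd_max_mismatch: int = 0,
    boundary_slop: int = 40,
    id_prefix: str = "smart",
) -> ValidationResult:
    """Promote candidate repeat pairs to complete element calls.

    A pair becomes a ``complete`` call iff the ``tsd_len`` bases immediately
    upstream of the element equal the ``tsd_len`` bases immediately
    downstream (within ``tsd_max_mismatch``), and -- when ``require_motif``
    -- the element begins TGT and ends ACA. The maximal-identity repeat
    window need not coincide with the element termini (it can drift into
    flanking sequence by up to roughly ``min_identity/(1-min_identity)``
    mismatch-buffered bases while staying above threshold), so boundaries
    are refined by searching for a TGT start / ACA end within
    ``boundary_slop`` bp of the window edges whose flanks duplicate; the
    joint motif+TSD requirement makes a spurious refinement vanishingly
    unlikely. Failed pairs are reported with a reason
    (``motif`` | ``tsd_mismatch`` | ``edge_unresolved``).
    """
    seq = genome.sequence
    calls: list[ElementCall] = []
    rejected: list[tuple[CandidatePair, str]] = []
    counter = 0
    for pair in pairs:
        s0, e0 = pair.span
        if require_motif:
            starts = [
                s for s in range(max(0, s0 - boundary_slop), s0 + boundary_slop + 1)
                if seq[s : s + 3] == "TGT"
            ]
            ends = [
                e for e in range(max(3, e0 - boundary_slop), min(len(seq), e0 + boundary_slop) + 1)
                if seq[e - 3 : e] == "ACA"
            ]
            if not starts or not ends:
                rejected.append((pair, "motif"))
                continue
        else:
            starts, ends = [s0], [e0]
        # try boundary pairs nearest the raw window first
        pairs_se = sorted(
            ((s, e) for s in starts for e in ends if e - s >= 2 * 3),
            key=lambda se: abs(se[0] - s0) + abs(se[1] - e0),
        )
        accepted = None
        best_mismatch = tsd_len + 1
        for s, e in pairs_se:
            if s < tsd_len or e + tsd_len > len(seq):
                continue
            up = seq[s - tsd_len : s]
            down = seq[e : e + tsd_len]
            mism = sum(1 for x, y in zip(up, down) if x != y)
            if mism <= tsd_max_mismatch and "N" not in up:
                accepted = (s, e, up)
                break
            best_mismatch = min(best_mismatch, mism)
        if accepted is None:
            # best-effort diagnostics: a near-miss duplication at
            # motif-consistent boundaries points at the TSD, anything worse
            # at absent termini; raw spans without flanks are edge cases
            if s0 < tsd_len or e0 + tsd_len > len(seq):
                reason = "edge_unresolved"
            elif best_mismatch <= tsd_max_mismatch + 1:
                reason = "tsd_mismatch"
            elif require_motif and not (
                seq[s0 : s0 + 3] == "TGT" and seq[e0 - 3 : e0] == "ACA"
            ):
                reason = "motif"
            elif best_mismatch <= tsd_len:
                reason = "tsd_mismatch"
            else:
                reason = "motif"
            rejected.append((pair, reason))
            continue
        s, e, tsd = accepted
        # shift the repeat window onto the refined boundaries
        ltr_len = pair.ltr_length + (s0 - s) + (e - e0)
        ltr_len = max(3, min(ltr_len, (e - s) // 2))
        counter += 1
        calls.append(
            ElementCall(
                id=f"{id_prefix}_{genome.name}_{counter:04d}",
                chrom=genome.name,
                start=s,
                end=e,
                cls="complete",
                strand="+",
                source="de_novo",
                ltr5=(s, s + ltr_len),
                ltr3=(e - ltr_len, e),
                tsd=tsd,
                identity=pair.repeat_identity,
            )
        )
    return ValidationResult(calls=calls, rejected=rejected)


def detect_elements(genome: GenomeRecord, **kwargs) -> ValidationResult:
    """Convenience: candidate scan followed by structural validation."""
    detect_keys = {
        "min_ltr", "min_internal", "max_element", "min_identity",
        "max_n_fraction", "resolve_overlaps",
    }
    val_keys = {"tsd_len", "require_motif", "tsd_max_mismatch", "boundary_slop", "id_prefix"}
    unknown = set(kwargs) - detect_keys - val_keys
    if unknown:
        raise TypeError(f"unknown options: {sorted(unknown)}")
    pairs = find_candidate_pairs(
        genome, **{k: v for k, v in kwargs.items() if k in detect_keys}
    )
    return validate_candidates(
        pairs, genome, **{k: v for k, v in kwargs.items() if k in val_keys}
    )
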
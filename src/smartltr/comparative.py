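"""Insertion-polymorphism calling between two assemblies.

For an element annotated in a *carrier* assembly, the 200-bp flanks on each
side are anchored in the *other* assembly by local alignment. An insertion
duplicates its 5-bp target site, so the pre-insertion ("empty") allele
carries exactly one TSD copy at the junction: when the two flank anchors
abut with a single TSD copy between them the call is ``new_insertion``;
when an element-length homologous insert lies between the anchors it is
``shared``; anything else (missing or multi-mapping flanks, inconsistent
anchor geometry) is surfaced as ``unresolved`` rather than silently
filtered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import _align
from .io_formats import ElementCall, GenomeRecord


@dataclass
class PolymorphismCall:
    element_id: str
    status: str  # new_insertion | shared | unresolved
    reason: str = ""
    tsd: str | None = None
    empty_site_tsd: bool = False
    other_chrom: str | None = None
    other_pos: int | None = None


def _anchor_flank(flank: str, other: list[GenomeRecord], min_identity: float):
    """Return all acceptable anchor sites of a flank in the other assembly."""
    anchors = []
    for rec in other:
        for h in _align.local_hits(
            rec.sequence, flank, k=12,
            match=1, mismatch=-1, gap_open=-5, gap_extend=-1,
            min_len=int(0.8 * len(flank)),
        ):
            covered = h.query_end - h.query_start
            if h.identity >= min_identity and covered >= 0.9 * len(flank):
                anchors.append((rec, h))
    return anchors


def call_polymorphism(
    call: ElementCall,
    carrier: list[GenomeRecord],
    other: list[GenomeRecord],
    flank: int = 200,
    min_flank_identity: float = 0.9,
    tsd_len: int = 5,
) -> PolymorphismCall:
    """Classify one element as new_insertion / shared / unresolved.

    The carrier's left flank ends with the upstream TSD copy and the right
    flank begins with the downstream copy, so at an empty site the two
    anchors overlap by exactly one TSD.
    """
    carrier_rec = next(r for r in carrier if r.name == call.chrom)
    seq = carrier_rec.sequence
    if call.start < flank or call.end + flank > len(seq):
        raise ValueError(f"{call.id}: needs {flank} bp of flank on both sides")
    left = seq[call.start - flank : call.start]
    right = seq[call.end : call.end + flank]
    tsd = call.tsd or seq[call.start - tsd_len : call.start]
    element_len = call.end - call.start
    element_seq = seq[call.start : call.end]

    left_anchors = _anchor_flank(left, other, min_flank_identity)
    right_anchors = _anchor_flank(right, other, min_flank_identity)
    if len(left_anchors) >= 2 or len(right_anchors) >= 2:
        return PolymorphismCall(call.id, "unresolved", reason="ambiguous_flanks", tsd=tsd)
    if not left_anchors or not right_anchors:
        return PolymorphismCall(call.id, "unresolved", reason="anchor_failure", tsd=tsd)
    (lrec, lh), (rrec, rh) = left_anchors[0], right_anchors[0]
    if lrec.name != rrec.name:
        return PolymorphismCall(call.id, "unresolved", reason="split_chromosomes", tsd=tsd)
    oseq = lrec.sequence
    # project alignment ends onto the flank termini
    x = lh.subject_end + (flank - lh.query_end)   # where the left flank ends
    y = rh.subject_start - rh.query_start         # where the right flank starts
    gap = y - x
    if gap >= 0.5 * element_len:
        insert = oseq[x:y]
        sites, mm = _align.global_divergence_counts(element_seq, insert)
        if (
            abs(gap - element_len) <= 0.2 * element_len + tsd_len
            and sites > 0
            and (sites - mm) / sites >= 0.7
        ):
            return PolymorphismCall(
                call.id, "shared", tsd=tsd, other_chrom=lrec.name, other_pos=x,
            )
        return PolymorphismCall(
            call.id, "unresolved", reason="non_homologous_insert", tsd=tsd,
            other_chrom=lrec.name, other_pos=x,
        )
    if -tsd_len <= gap <= 0.1 * element_len:
        junction = oseq[min(x, y) - tsd_len : max(x, y) + tsd_len]
        single_copy = junction.count(tsd) == 1 if tsd else False
        if single_copy:
            return PolymorphismCall(
                call.id, "new_insertion", tsd=tsd, empty_site_tsd=True,
                other_chrom=lrec.name, other_pos=min(x, y),
            )
        return PolymorphismCall(
            call.id, "unresolved", reason="tsd_ambiguous", tsd=tsd,
            other_chrom=lrec.name, other_pos=min(x, y),
        )
    return PolymorphismCall(
        call.id, "unresolved", reason="inconsistent_anchors", tsd=tsd,
        other_chrom=lrec.name, other_pos=x,
    )


def compare_assemblies(
    calls: list[ElementCall],
    carrier: list[GenomeRecord],
    other: list[GenomeRecord],
    **kwargs,
) -> pd.DataFrame:
    rows = []
    for call in calls:
        try:
            pc = call_polymorphism(call, carrier, other, **kwargs)
        except ValueError:
            pc = PolymorphismCall(call.id, "unresolved", reason="edge")
        rows.append({
            "element_id": pc.element_id,
            "status": pc.status,
            "reason": pc.reason if pc.reason else pd.NA,
            "tsd": pc.tsd if pc.tsd else pd.NA,
            "empty_site_tsd": pc.empty_site_tsd,
            "other_chrom": pc.other_chrom if pc.other_chrom else pd.NA,
            "other_pos": pc.other_pos if pc.other_pos is not None else pd.NA,
        })
    return pd.DataFrame(rows)
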
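"""Classify each element's position relative to gene models.

Categories (one per element): ``exon`` (coding exon), ``utr``, ``intron``,
``flank_1kb`` (element boundary within 1 kb of a gene span, either side,
strand-agnostic), ``other`` (overlaps a user-supplied repeat mask or is
flagged multi-copy), ``single_copy`` (none of the above). Precedence inside
a gene body is exon > utr > intron decided by the feature type with the
largest overlap, ties to the higher-precedence type.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import ElementCall, GeneModel
from .summary_stats import round_half_up

CATEGORIES = ("exon", "utr", "intron", "flank_1kb", "single_copy", "other")


@dataclass
class ContextCall:
    element_id: str
    category: str
    gene_id: str | None = None
    distance_bp: int | None = None  # signed; negative = upstream of the gene
    overlap_exon: int = 0
    overlap_utr: int = 0
    overlap_intron: int = 0
    flags: str = ""


def _overlap(span: tuple[int, int], ivs: list[tuple[int, int]]) -> int:
    s, e = span
    return sum(max(0, min(b, e) - max(a, s)) for a, b in ivs)


def build_mask(intervals: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    """Build a per-chromosome repeat mask from (chrom, start, end) triples."""
    mask: dict[str, IntervalTree] = {}
    for chrom, s, e in intervals:
        mask.setdefault(chrom, IntervalTree()).addi(s, e)
    return mask


def classify_context(
    call: ElementCall,
    genes: list[GeneModel],
    repeats_mask: dict[str, IntervalTree] | None = None,
    flank: int = 1000,
    multi_copy: bool = False,
) -> ContextCall:
    """Assign one genic category to an element call.

    ``multi_copy`` lets the caller flag elements known to sit in
    multiple-copy regions (copy-number estimation itself is out of scope);
    such elements fall into ``other`` like mask overlaps do.
    """
    span = call.span
    chrom_genes = [g for g in genes if g.chrom == call.chrom]
    if genes and not chrom_genes:
        flags = "chrom_not_annotated"
    else:
        flags = ""
    best = None  # (overlap, precedence_rank, gene)
    per_type = {"exon": 0, "utr": 0, "intron": 0}
    for g in chrom_genes:
        ovs = {
            "exon": _overlap(span, g.cds),
            "utr": _overlap(span, g.utr5 + g.utr3),
            "intron": _overlap(span, g.introns),
        }
        for rank, t in enumerate(("exon", "utr", "intron")):
            if ovs[t] > 0:
                per_type[t] = max(per_type[t], ovs[t])
                key = (ovs[t], -rank)
                if best is None or key > best[0]:
                    best = (key, t, g)
    if best is not None:
        _, category, gene = best
        return ContextCall(
            element_id=call.id,
            category=category,
            gene_id=gene.gene_id,
            distance_bp=0,
            overlap_exon=per_type["exon"],
            overlap_utr=per_type["utr"],
            overlap_intron=per_type["intron"],
            flags=flags,
        )
    # no gene-body overlap: nearest gene within the flank window?
    nearest = None
    for g in chrom_genes:
        gs, ge = g.span
        if span[0] >= ge:
            dist = span[0] - ge  # element downstream of gene
        elif span[1] <= gs:
            dist = -(gs - span[1])  # upstream
        else:
            dist = 0
        if nearest is None or abs(dist) < abs(nearest[0]):
            nearest = (dist, g)
    if nearest is not None and abs(nearest[0]) <= flank:
        return ContextCall(
            element_id=call.id,
            category="flank_1kb",
            gene_id=nearest[1].gene_id,
            distance_bp=nearest[0],
            flags=flags,
        )
    in_mask = False
    if repeats_mask is not None:
        tree = repeats_mask.get(call.chrom)
        in_mask = bool(tree is not None and tree.overlap(span[0], span[1]))
    if in_mask or multi_copy:
        return ContextCall(call.id, "other", flags=flags)
    return ContextCall(call.id, "single_copy", flags=flags)


def summarize_contexts(contexts: list[ContextCall], total: int) -> pd.DataFrame:
    """Category counts and percentages (half-up, one decimal), plus a
    combined in-or-near-genes row rounded to the nearest integer percent.

    ``total`` may exceed the number of classified calls (fragments may be
    excluded upstream); percentages use ``total`` as denominator.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in contexts:
        counts[c.category] += 1
    rows = [
        {"category": cat, "count": n, "percent": round_half_up(100.0 * n / total, 1)}
        for cat, n in counts.items()
    ]
    near = sum(counts[c] for c in ("exon", "utr", "intron", "flank_1kb"))
    rows.append({
        "category": "in_or_near_genes",
        "count": near,
        "percent": round_half_up(100.0 * near / total, 0),
    })
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def contexts_frame(contexts: list[ContextCall]) -> pd.DataFrame:
    return pd.DataFrame([{
        "element_id": c.element_id,
        "category": c.category,
        "gene_id": c.gene_id if c.gene_id else pd.NA,
        "distance_bp": c.distance_bp if c.distance_bp is not None else pd.NA,
        "flags": c.flags if c.flags else pd.NA,
    } for c in contexts])
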
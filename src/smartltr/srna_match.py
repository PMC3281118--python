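"""Exact-match mapping of small RNAs to a genome.

Reads (RNA or DNA alphabet) are matched at 100% identity against both
strands of the genome; every occurrence is reported. A palindromic read
(equal to its own reverse complement) matches both strands at the same
locus and is counted once, on the plus strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from ._align import revcomp
from .io_formats import ElementCall, GenomeRecord

MIN_LEN, MAX_LEN = 18, 30


@dataclass
class SRNAHit:
    srna_id: str
    length: int
    chrom: str
    position: int  # 0-based start of the genomic site (forward coordinates)
    strand: str
    overlaps_element: bool = False


def _occurrences(haystack: str, needle: str):
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def map_exact(
    srnas: list[tuple[str, str]], genome: list[GenomeRecord]
) -> list[SRNAHit]:
    """Report every exact genomic occurrence of each sRNA, both strands.

    ``srnas`` is a list of (id, sequence) pairs; U is converted to T before
    matching. Reads with characters outside ACGU/T, or with lengths outside
    18-30 nt, are skipped with a warning.
    """
    hits: list[SRNAHit] = []
    for rid, raw in srnas:
        seq = raw.upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            warnings.warn(f"sRNA {rid}: non-ACGU/T characters; skipped", stacklevel=2)
            continue
        if not MIN_LEN <= len(seq) <= MAX_LEN:
            warnings.warn(f"sRNA {rid}: length {len(seq)} outside 18-30 nt; skipped",
                          stacklevel=2)
            continue
        rc = revcomp(seq)
        palindromic = rc == seq
        for rec in genome:
            for pos in _occurrences(rec.sequence, seq):
                hits.append(SRNAHit(rid, len(seq), rec.name, pos, "+"))
            if not palindromic:
                for pos in _occurrences(rec.sequence, rc):
                    hits.append(SRNAHit(rid, len(seq), rec.name, pos, "-"))
    hits.sort(key=lambda h: (h.srna_id, h.chrom, h.position, h.strand))
    return hits


def summarize_srna(
    hits: list[SRNAHit], elements: list[ElementCall]
) -> tuple[pd.DataFrame, float]:
    """Per-sRNA site counts split by element overlap, plus the mean total.

    Returns (table, mean_sites). The table has one row per sRNA with
    columns transposon / other / total (transposon + other = total) and a
    ``unique`` flag for single-site reads. ``mean_sites`` is NaN when there
    are no hits.
    """
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.chrom, IntervalTree()).addi(el.start, el.end)
    per: dict[str, dict[str, int]] = {}
    for h in hits:
        tree = trees.get(h.chrom)
        h.overlaps_element = bool(tree is not None and tree.overlap(h.position, h.position + h.length))
        d = per.setdefault(h.srna_id, {"transposon": 0, "other": 0})
        d["transposon" if h.overlaps_element else "other"] += 1
    rows = [
        {
            "srna_id": rid,
            "transposon": d["transposon"],
            "other": d["other"],
            "total": d["transposon"] + d["other"],
            "unique": d["transposon"] + d["other"] == 1,
        }
        for rid, d in sorted(per.items())
    ]
    df = pd.DataFrame(rows, columns=["srna_id", "transposon", "other", "total", "unique"])
    mean_sites = float(df["total"].mean()) if len(df) else float("nan")
    return df, mean_sites
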
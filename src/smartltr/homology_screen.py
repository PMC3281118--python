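"""Library-driven discovery of homologous elements and their classification.

A reference library of complete elements (with annotated LTR / internal
spans) is aligned locally against a genome. Hits above the score and length
cutoffs are clustered by proximity and each cluster is classified:

* ``complete`` - both LTR regions of the library element covered and the
  genomic span flanked by a duplicated target site (TSD);
* ``solo_LTR`` - exactly one LTR covered, no internal-region coverage,
  TSDs verified, span close to one LTR length;
* ``fragment`` - anything else that passed the screen.

Scoring is match +10 / mismatch -10 / gap open -50 / gap extend -10 with a
default score cutoff of 250 and minimum hit length of 50 bp, so that exact
matches longer than 25 bp clear the score cutoff and the length filter is
the binding constraint for short hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import _align
from .io_formats import ElementCall, GenomeRecord

log = logging.getLogger(__name__)

DEFAULT_SCORING = {"match": 10, "mismatch": -10, "gap_open": -50, "gap_extend": -10}


@dataclass
class LibraryElement:
    """A complete reference element whose LTR/internal spans tile it exactly."""

    id: str
    sequence: str
    ltr5_span: tuple[int, int]
    internal_span: tuple[int, int]
    ltr3_span: tuple[int, int]

    def __post_init__(self):
        a, b, c = self.ltr5_span, self.internal_span, self.ltr3_span
        if not (a[0] == 0 and a[1] == b[0] and b[1] == c[0] and c[1] == len(self.sequence)):
            raise ValueError(f"{self.id}: LTR/internal spans must tile the sequence")

    @property
    def ltr_length(self) -> int:
        return self.ltr5_span[1] - self.ltr5_span[0]


def load_library(fasta_path, spans_path) -> list[LibraryElement]:
    """Library FASTA plus a TSV of columns id, ltr5_end, internal_end."""
    from .io_formats import read_fasta

    spans = pd.read_csv(spans_path, sep="\t").set_index("id")
    lib = []
    for rec in read_fasta(fasta_path):
        row = spans.loc[rec.name]
        a, b = int(row["ltr5_end"]), int(row["internal_end"])
        lib.append(LibraryElement(
            rec.name, rec.sequence, (0, a), (a, b), (b, rec.length)
        ))
    return lib


@dataclass
class HomologyHit:
    chrom: str
    start: int
    end: int
    library_id: str
    library_span: tuple[int, int]
    strand: str
    score: float
    identity: float
    library_blocks: list[tuple[int, int]]


def screen_genome(
    genome: list[GenomeRecord],
    library: list[LibraryElement],
    min_score: float = 250,
    min_len: int = 50,
    scoring: dict | None = None,
    k: int = 11,
) -> list[HomologyHit]:
    """Local-alignment screen of a genome against a reference library.

    Both strands are searched. Overlapping hits from different library
    members are merged to the best-scoring representative.
    """
    if not library:
        raise ValueError("library must be non-empty")
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    hits: list[HomologyHit] = []
    for rec in genome:
        per_record: list[HomologyHit] = []
        for lib in library:
            for strand, query in (("+", lib.sequence), ("-", _align.revcomp(lib.sequence))):
                for h in _align.local_hits(
                    rec.sequence, query, k=k,
                    match=sc["match"], mismatch=sc["mismatch"],
                    gap_open=sc["gap_open"], gap_extend=sc["gap_extend"],
                    min_score=min_score, min_len=min_len,
                ):
                    qlen = len(query)
                    if strand == "-":
                        blocks = [(qlen - b, qlen - a) for a, b in reversed(h.query_blocks)]
                        q_span = (qlen - h.query_end, qlen - h.query_start)
                    else:
                        blocks = h.query_blocks
                        q_span = (h.query_start, h.query_end)
                    per_record.append(HomologyHit(
                        chrom=rec.name,
                        start=h.subject_start,
                        end=h.subject_end,
                        library_id=lib.id,
                        library_span=q_span,
                        strand=strand,
                        score=h.score,
                        identity=h.identity,
                        library_blocks=blocks,
                    ))
        hits.extend(_merge_representatives(per_record))
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits


def _merge_representatives(hits: list[HomologyHit]) -> list[HomologyHit]:
    """Among genome-overlapping hits keep the best-scoring one."""
    hits = sorted(hits, key=lambda h: (-h.score, h.start))
    kept: list[HomologyHit] = []
    for h in hits:
        overlap = False
        for o in kept:
            inter = min(h.end, o.end) - max(h.start, o.start)
            if inter > 0.5 * min(h.end - h.start, o.end - o.start):
                overlap = True
                break
        if not overlap:
            kept.append(h)
    return kept


def _region_coverage(blocks, region) -> float:
    a, b = region
    if b <= a:
        return 0.0
    cov = sum(max(0, min(e, b) - max(s, a)) for s, e in blocks)
    return cov / (b - a)


def classify_hits(
    hits: list[HomologyHit],
    genome: list[GenomeRecord],
    library: list[LibraryElement],
    tsd_len: int = 5,
    ltr_cov_min: float = 0.80,
    merge_gap: int = 50,
    solo_span_range: tuple[float, float] = (0.9, 1.05),
    tsd_slop: int = 3,
    id_prefix: str = "hom",
) -> list[ElementCall]:
    """Cluster screen hits and classify complete / solo-LTR / fragment.

    Hits within ``merge_gap`` bp on the same chromosome and strand form one
    cluster (tolerates nested interruptions); library-coordinate coverage of
    the cluster decides the class and a duplicated ``tsd_len``-mer on the
    genomic flanks confirms it. Every cluster yields exactly one call.
    """
    by_name = {g.name: g for g in genome}
    by_lib = {l.id: l for l in library}
    clusters = _cluster(hits, merge_gap)
    calls: list[ElementCall] = []
    for i, cl in enumerate(sorted(clusters, key=lambda c: (c[0].chrom, c[0].start))):
        chrom = cl[0].chrom
        start = min(h.start for h in cl)
        end = max(h.end for h in cl)
        lib = by_lib[max(cl, key=lambda h: h.score).library_id]
        blocks = [b for h in cl for b in h.library_blocks]
        cov5 = _region_coverage(blocks, lib.ltr5_span)
        cov_int = _region_coverage(blocks, lib.internal_span)
        cov3 = _region_coverage(blocks, lib.ltr3_span)
        identity = max(h.identity for h in cl)
        strand = cl[0].strand
        seq = by_name[chrom].sequence
        tsd, tsd_span, edge = _find_tsd(seq, start, end, tsd_len, tsd_slop)
        flags = []
        if edge:
            flags.append("edge")
        n_ltrs_covered = (cov5 >= ltr_cov_min) + (cov3 >= ltr_cov_min)
        span_len = end - start
        cls = "fragment"
        ltr5 = ltr3 = None
        if edge:
            cls = "fragment"
        elif n_ltrs_covered == 2 and tsd is not None:
            cls = "complete"
            ltr5 = (start, start + lib.ltr_length)
            ltr3 = (end - lib.ltr_length, end)
        elif (
            n_ltrs_covered == 1
            and cov_int < 0.2
            and tsd is not None
            and solo_span_range[0] * lib.ltr_length
            <= span_len
            <= solo_span_range[1] * lib.ltr_length
        ):
            cls = "solo_LTR"
        if cls in ("complete", "solo_LTR") and tsd_span is not None:
            start, end = tsd_span
            if cls == "complete":
                ltr5 = (start, start + lib.ltr_length)
                ltr3 = (end - lib.ltr_length, end)
        calls.append(ElementCall(
            id=f"{id_prefix}_{chrom}_{i + 1:04d}",
            chrom=chrom,
            start=start,
            end=end,
            cls=cls,
            strand=strand,
            source="homology",
            ltr5=ltr5,
            ltr3=ltr3,
            tsd=tsd,
            identity=identity,
            flags=",".join(flags),
        ))
    return calls


def _cluster(hits, merge_gap):
    clusters: list[list[HomologyHit]] = []
    for h in sorted(hits, key=lambda h: (h.chrom, h.start)):
        if (
            clusters
            and clusters[-1][0].chrom == h.chrom
            and clusters[-1][0].strand == h.strand
            and h.start - max(x.end for x in clusters[-1]) <= merge_gap
        ):
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def _find_tsd(seq, start, end, tsd_len, slop):
    """Look for a duplicated tsd_len-mer flanking [start,end), allowing the
    alignment to have missed the exact edge by up to ``slop`` bp.

    Returns (tsd, refined_span, at_edge)."""
    if start < tsd_len or end + tsd_len > len(seq):
        return None, None, True
    offsets = sorted(
        ((ds, de) for ds in range(-slop, slop + 1) for de in range(-slop, slop + 1)),
        key=lambda o: abs(o[0]) + abs(o[1]),
    )
    for ds, de in offsets:
        s, e = start + ds, end + de
        if s < tsd_len or e + tsd_len > len(seq) or e <= s:
            continue
        up = seq[s - tsd_len : s]
        down = seq[e : e + tsd_len]
        if up == down and "N" not in up:
            return up, (s, e), False
    return None, None, False
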
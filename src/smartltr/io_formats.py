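"""Reading and writing the standard formats the pipeline touches.

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive convention of GFF3 (and back) happens only at file boundaries.
BED stays 0-based half-open on disk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

GENOME_ALPHABET = set("ACGTN")

ELEMENT_CLASSES = ("complete", "solo_LTR", "fragment")

# SO-flavoured feature types used when emitting element calls as GFF3
_GFF_TYPE = {
    "complete": "LTR_retrotransposon",
    "solo_LTR": "solo_LTR",
    "fragment": "transposable_element_fragment",
}
_GFF_TYPE_INV = {v: k for k, v in _GFF_TYPE.items()}


class FastaParseError(ValueError):
    pass


@dataclass
class GenomeRecord:
    """A named chromosome/contig: uppercase sequence over {A,C,G,T,N}.

    ``mask`` flags positions that were lowercase (soft-masked) in the source
    file; it is None when nothing was masked.
    """

    name: str
    sequence: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise ValueError(f"record {self.name!r}: illegal characters {sorted(bad)}")
        if self.mask is not None and len(self.mask) != len(self.sequence):
            raise ValueError("mask length != sequence length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A protein-coding gene model with derived introns and UTRs.

    Exons are the transcript exons (UTR included); ``cds`` the coding
    intervals. Introns are exactly the gaps between consecutive exons and
    UTRs are the exonic set-difference with the CDS, never read from the
    annotation (dialects disagree on UTR feature lines).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    introns: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @classmethod
    def from_exons_cds(cls, gene_id, chrom, strand, exons, cds) -> "GeneModel":
        exons = sorted((int(a), int(b)) for a, b in exons)
        cds = sorted((int(a), int(b)) for a, b in cds)
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError(f"gene {gene_id}: overlapping exons")
        introns = [(b1, a2) for (_, b1), (a2, _) in zip(exons, exons[1:]) if a2 > b1]
        utr = _interval_difference(exons, cds)
        if cds:
            cds_start, cds_end = cds[0][0], cds[-1][1]
            left = [iv for iv in utr if iv[1] <= cds_start]
            right = [iv for iv in utr if iv[0] >= cds_end]
        else:
            left, right = utr, []
        if strand == "-":
            left, right = right, left
        return cls(gene_id, chrom, strand, exons, cds, utr5=left, utr3=right, introns=introns)


def _interval_difference(minuend, subtrahend):
    """Set difference over sorted non-overlapping interval lists."""
    out = []
    for a, b in minuend:
        cur = a
        for c, d in subtrahend:
            if d <= cur or c >= b:
                continue
            if c > cur:
                out.append((cur, c))
            cur = max(cur, d)
        if cur < b:
            out.append((cur, b))
    return out


@dataclass
class ElementCall:
    """One annotated retrotransposon locus (complete, solo-LTR or fragment)."""

    id: str
    chrom: str
    start: int
    end: int
    cls: str
    strand: str = "+"
    source: str = "de_novo"  # de_novo | homology
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None
    tsd: str | None = None
    identity: float | None = None
    age_mya: float | None = None
    flags: str = ""

    def __post_init__(self):
        if self.cls not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.cls!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span [{self.start},{self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeRecord]:
    """Read a (possibly wrapped) multi-FASTA into GenomeRecords.

    Sequences are uppercased; lowercase (soft-masked) runs are preserved as a
    boolean mask. Malformed headers or illegal characters raise
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        mask = np.fromiter((c.islower() for c in raw), dtype=bool, count=len(raw))
        records.append(
            GenomeRecord(rec.id, raw.upper(), mask=mask if mask.any() else None)
        )
        if rec.id in seen:
            raise FastaParseError(f"duplicate record name {rec.id!r}")
        seen.add(rec.id)
    if not records:
        warnings.warn(f"{path}: empty FASTA", stacklevel=2)
    return records


def _validate_fasta_lines(path: Path) -> None:
    legal = GENOME_ALPHABET | {c.lower() for c in GENOME_ALPHABET}
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                in_record = True
                continue
            if not in_record:
                raise FastaParseError(f"{path}:{lineno}: sequence before any header")
            bad = set(line) - legal
            if bad:
                raise FastaParseError(
                    f"{path}:{lineno}: illegal character(s) {sorted(bad)}"
                )


def write_fasta(records: list[GenomeRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            seq = rec.sequence
            if rec.mask is not None:
                seq = "".join(
                    c.lower() if m else c for c, m in zip(seq, rec.mask)
                )
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into GeneModels (one per mRNA).

    GFF3's 1-based inclusive coordinates are converted to 0-based half-open.
    Introns and UTRs are derived, never read. Genes whose exons fall outside
    the gene span are skipped with a log entry; exon/CDS features lacking a
    Parent are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
        if not exons:
            log.warning("mRNA %s has no exons; skipped", mrna.id)
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        span = (parents[0].start - 1, parents[0].end) if parents else None
        if span is not None and any(a < span[0] or b > span[1] for a, b in exons):
            log.warning("gene %s: exon outside gene span; skipped", mrna.id)
            continue
        try:
            models.append(
                GeneModel.from_exons_cds(mrna.id, mrna.seqid, mrna.strand, exons, cds)
            )
        except ValueError as exc:
            log.warning("skipping %s: %s", mrna.id, exc)
    return models


def write_genes_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tsmartltr\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}_g\n"
            )
            fh.write(
                f"{g.chrom}\tsmartltr\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Parent={g.gene_id}_g\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chrom}\tsmartltr\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            for a, b in g.cds:
                fh.write(
                    f"{g.chrom}\tsmartltr\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Element calls: GFF3 / BED6 / TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "id", "chrom", "start", "end", "class", "strand", "source",
    "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end",
    "tsd", "identity", "age_mya", "flags",
]


def write_elements(calls: list[ElementCall], path, fmt: str = "tsv") -> None:
    """Write element calls as GFF3 (1-based inclusive), BED6 or TSV.

    A round trip through :func:`read_elements` reproduces coordinates and
    classes exactly.
    """
    if fmt == "tsv":
        _elements_frame(calls).to_csv(path, sep="\t", index=False)
    elif fmt == "bed":
        with open(path, "w") as fh:
            for c in calls:
                score = 0 if c.identity is None else int(round(c.identity * 1000))
                fh.write(
                    f"{c.chrom}\t{c.start}\t{c.end}\t{c.id}|{c.cls}\t{score}\t{c.strand}\n"
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in calls:
                attrs = [f"ID={c.id}", f"smart_class={c.cls}"]
                if c.tsd:
                    attrs.append(f"tsd={c.tsd}")
                if c.age_mya is not None:
                    attrs.append(f"age_mya={c.age_mya}")
                if c.ltr5:
                    attrs.append(f"ltr5={c.ltr5[0]}-{c.ltr5[1]}")
                if c.ltr3:
                    attrs.append(f"ltr3={c.ltr3[0]}-{c.ltr3[1]}")
                if c.identity is not None:
                    attrs.append(f"identity={c.identity:.6g}")
                attrs.append(f"source_method={c.source}")
                if c.flags:
                    attrs.append(f"flags={c.flags}")
                fh.write(
                    f"{c.chrom}\tsmartltr\t{_GFF_TYPE[c.cls]}\t{c.start + 1}\t{c.end}"
                    f"\t.\t{c.strand}\t.\t{';'.join(attrs)}\n"
                )
    else:
        raise ValueError(f"unknown format {fmt!r} (expected gff3, bed or tsv)")


def _elements_frame(calls: list[ElementCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "id": c.id, "chrom": c.chrom, "start": c.start, "end": c.end,
            "class": c.cls, "strand": c.strand, "source": c.source,
            "ltr5_start": c.ltr5[0] if c.ltr5 else pd.NA,
            "ltr5_end": c.ltr5[1] if c.ltr5 else pd.NA,
            "ltr3_start": c.ltr3[0] if c.ltr3 else pd.NA,
            "ltr3_end": c.ltr3[1] if c.ltr3 else pd.NA,
            "tsd": c.tsd if c.tsd else pd.NA,
            "identity": c.identity if c.identity is not None else pd.NA,
            "age_mya": c.age_mya if c.age_mya is not None else pd.NA,
            "flags": c.flags if c.flags else pd.NA,
        })
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def read_elements(path, fmt: str = "tsv") -> list[ElementCall]:
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        calls = []
        for _, row in df.iterrows():
            ltr5 = (
                (int(row["ltr5_start"]), int(row["ltr5_end"]))
                if pd.notna(row["ltr5_start"]) else None
            )
            ltr3 = (
                (int(row["ltr3_start"]), int(row["ltr3_end"]))
                if pd.notna(row["ltr3_start"]) else None
            )
            calls.append(ElementCall(
                id=str(row["id"]), chrom=str(row["chrom"]), start=int(row["start"]),
                end=int(row["end"]), cls=str(row["class"]),
                strand=str(row["strand"]), source=str(row["source"]),
                ltr5=ltr5, ltr3=ltr3,
                tsd=str(row["tsd"]) if pd.notna(row["tsd"]) else None,
                identity=float(row["identity"]) if pd.notna(row["identity"]) else None,
                age_mya=float(row["age_mya"]) if pd.notna(row["age_mya"]) else None,
                flags=str(row["flags"]) if pd.notna(row["flags"]) else "",
            ))
        return calls
    if fmt == "bed":
        calls = []
        with open(path) as fh:
            for line in fh:
                chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
                cid, cls = name.rsplit("|", 1)
                calls.append(ElementCall(
                    id=cid, chrom=chrom, start=int(start), end=int(end),
                    cls=cls, strand=strand,
                ))
        return calls
    if fmt == "gff3":
        calls = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                chrom, _src, ftype, start, end, _score, strand, _phase, attr = (
                    line.rstrip("\n").split("\t")
                )
                attrs = dict(kv.split("=", 1) for kv in attr.split(";") if "=" in kv)
                ltr5 = ltr3 = None
                if "ltr5" in attrs:
                    a, b = attrs["ltr5"].split("-")
                    ltr5 = (int(a), int(b))
                if "ltr3" in attrs:
                    a, b = attrs["ltr3"].split("-")
                    ltr3 = (int(a), int(b))
                calls.append(ElementCall(
                    id=attrs["ID"], chrom=chrom, start=int(start) - 1, end=int(end),
                    cls=attrs.get("smart_class", _GFF_TYPE_INV.get(ftype, "fragment")),
                    strand=strand, source=attrs.get("source_method", "de_novo"),
                    ltr5=ltr5, ltr3=ltr3, tsd=attrs.get("tsd"),
                    identity=float(attrs["identity"]) if "identity" in attrs else None,
                    age_mya=float(attrs["age_mya"]) if "age_mya" in attrs else None,
                    flags=attrs.get("flags", ""),
                ))
        return calls
    raise ValueError(f"unknown format {fmt!r} (expected gff3, bed or tsv)")
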
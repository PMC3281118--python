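"""Synthetic genomes with planted miniature LTR retrotransposons.

The generator emulates the anatomy the pipeline is built to recover: a
292-bp-scale element with two 85-bp LTRs carrying TGT...ACA termini, a
~122-bp internal region, and a 5-bp target-site duplication created at
insertion. Complete elements, solo-LTRs and truncated fragments are planted
into background DNA of tunable GC content, inside introns, within 1 kb of
genes, or in intergenic space, and every planted feature is recorded in a
truth table so detection, classification, dating, context and sRNA mapping
can all be scored against known answers.

LTR ageing follows a Jukes-Cantor substitution process: each LTR copy
receives independent per-site Poisson substitutions so that the expected
whole-LTR divergence between the two copies is 2*r*T. The terminal 3-bp
motifs are exempt from mutation (they are what makes the element class
recognisable at all); the per-site rate on the remaining sites is scaled by
L/(L-6) so the whole-LTR expectation is preserved despite the exemption.
No indels are simulated - the dating formula assumes substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._align import revcomp
from .io_formats import GeneModel, GenomeRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MOTIF_EXEMPT = 3  # bp at each LTR end (TGT / ACA) never mutated
JC_DIVERGENCE_CAP = 0.70  # per-site; beyond this JC correction is unstable


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults mirror the element family the pipeline targets: 85-bp LTRs,
    122-bp internal region, 5-bp TSD, substitution rate 1.3e-8/site/year,
    ages up to 10 MYA, and the genic-context mix observed in rice
    (roughly 28% intronic, 20% within 1 kb of a gene, the rest intergenic).
    """

    genome_length: int = 300_000
    gc_fraction: float = 0.44
    n_complete: int = 20
    n_solo: int = 5
    n_fragment: int = 10
    ltr_length: int = 85
    internal_length: int = 122
    tsd_length: int = 5
    ages_mya: list[float] | None = None
    max_age_mya: float = 10.0
    rate_r: float = 1.3e-8
    n_genes: int = 20
    n_nested: int = 0
    frac_intron: float = 0.28
    frac_flank: float = 0.20
    min_spacing: int = 2500
    chrom_name: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.ltr_length < 50:
            raise SimulationConfigError("ltr_length must be >= 50")
        if not 0 <= self.gc_fraction <= 1:
            raise SimulationConfigError("gc_fraction must be in [0,1]")
        if self.n_nested > self.n_complete // 2:
            raise SimulationConfigError(
                "n_nested must not exceed half of n_complete (one distinct "
                "host per nested element, one nesting level)"
            )
        ages = self.ages_mya if self.ages_mya is not None else [self.max_age_mya]
        for a in ages:
            if a < 0:
                raise SimulationConfigError("ages must be non-negative")
            check_divergence_cap(a, self.rate_r)
        insert_bp = (self.n_complete + self.n_fragment) * self.element_length
        insert_bp += self.n_solo * self.ltr_length
        if insert_bp + self.total_features * self.min_spacing > 2 * self.genome_length:
            raise SimulationConfigError(
                "infeasible packing: features exceed genome length"
            )

    @property
    def element_length(self) -> int:
        return 2 * self.ltr_length + self.internal_length

    @property
    def total_features(self) -> int:
        return self.n_complete + self.n_solo + self.n_fragment


def check_divergence_cap(age_mya: float, rate_r: float) -> None:
    expected = 2.0 * rate_r * age_mya * 1e6
    if expected > JC_DIVERGENCE_CAP:
        raise SimulationConfigError(
            f"expected LTR divergence {expected:.3f}/site at {age_mya} MYA exceeds "
            f"the Jukes-Cantor reliability cap {JC_DIVERGENCE_CAP}"
        )


TRUTH_COLUMNS = [
    "id", "chrom", "start", "end", "class", "true_age_mya", "tsd", "context",
    "parent", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end", "motif_exempt",
]


def _rng_of(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return BASES[idx].tobytes().decode("ascii")


def mutate_sequence(
    seq: str,
    subs_per_site: float,
    rng,
    exempt_termini: bool = False,
) -> str:
    """Apply per-site Poisson substitutions with equal-rate (JC) replacement.

    Each substitution event replaces the base with one of the other three,
    uniformly, so multiple hits can revert - exactly the process the
    Jukes-Cantor correction inverts.
    """
    rng = _rng_of(rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    lam = np.full(n, subs_per_site, dtype=float)
    if exempt_termini and n > 2 * MOTIF_EXEMPT:
        lam *= n / (n - 2 * MOTIF_EXEMPT)
        lam[:MOTIF_EXEMPT] = 0.0
        lam[-MOTIF_EXEMPT:] = 0.0
    events = rng.poisson(lam)
    for i in np.nonzero(events)[0]:
        base = arr[i]
        for _ in range(events[i]):
            choices = BASES[BASES != base]
            base = rng.choice(choices)
        arr[i] = base
    return arr.tobytes().decode("ascii")


def age_ltrs(
    ltr: str, age_mya: float, rate_r: float, seed
) -> tuple[str, str]:
    """Diverge two copies of an LTR to a target age.

    Each copy accumulates substitutions independently with expectation
    ``rate_r * age_mya * 1e6`` per site, so the expected divergence between
    the copies is 2*r*T. Terminal TGT/ACA motifs are exempt; the remaining
    sites are up-weighted to preserve the whole-LTR expectation.
    """
    if age_mya < 0:
        raise SimulationConfigError("age must be non-negative")
    check_divergence_cap(age_mya, rate_r)
    rng = _rng_of(seed)
    lam = rate_r * age_mya * 1e6
    ltr5 = mutate_sequence(ltr, lam, rng, exempt_termini=True)
    ltr3 = mutate_sequence(ltr, lam, rng, exempt_termini=True)
    return ltr5, ltr3


@dataclass
class _Placement:
    feature_id: str
    cls: str
    context: str
    bg_pos: int          # insertion point in background coordinates
    insert: str          # full inserted string (element [+ TSD copy])
    element_offset: int  # element start within the inserted string
    element_len: int
    age: float
    tsd: str | None
    parent: str | None = None
    ltr_len: int | None = None
    children: list = field(default_factory=list)


def simulate_genome(
    config: SimConfig,
) -> tuple[list[GenomeRecord], list[GeneModel], pd.DataFrame]:
    """Generate (genome records, gene models, truth table).

    Deterministic given the config (identical config+seed gives
    byte-identical outputs). Raises :class:`SimulationConfigError` before
    producing any output when the requested features cannot be packed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    background = _random_seq(rng, config.genome_length, config.gc_fraction)

    ancestral_ltr = "TGT" + _random_seq(rng, config.ltr_length - 6, config.gc_fraction) + "ACA"
    ancestral_internal = _random_seq(rng, config.internal_length, config.gc_fraction)

    genes_bg = _place_genes(rng, config)
    placements = _plan_placements(rng, config, genes_bg)
    _build_inserts(rng, config, placements, background, ancestral_ltr, ancestral_internal)

    seq, final_pos = _assemble(background, placements)
    truth = _truth_table(config, placements, final_pos)
    # the family consensus every planted copy descends from; callers can use
    # it as a homology-screen library (e.g. truth.attrs["ancestral_element"])
    truth.attrs["ancestral_ltr"] = ancestral_ltr
    truth.attrs["ancestral_internal"] = ancestral_internal
    truth.attrs["ancestral_element"] = (
        ancestral_ltr + ancestral_internal + ancestral_ltr
    )
    mapper = _interval_mapper(placements)
    genes = [
        GeneModel.from_exons_cds(
            g.gene_id, config.chrom_name, g.strand,
            [mapper(iv) for iv in g.exons],
            [mapper(iv) for iv in g.cds],
        )
        for g in genes_bg
    ]
    records = [GenomeRecord(config.chrom_name, seq)]
    return records, genes, truth


# -- gene placement (background coordinates) --------------------------------

def _place_genes(rng, config: SimConfig) -> list[GeneModel]:
    genes: list[GeneModel] = []
    spans: list[tuple[int, int]] = []
    margin = 2200  # keeps 1-kb flank zones of neighbouring genes disjoint
    attempts = 0
    while len(genes) < config.n_genes and attempts < 200 * max(config.n_genes, 1):
        attempts += 1
        n_ex = int(rng.integers(3, 7))
        exon_lens = rng.integers(80, 301, size=n_ex)
        intron_lens = rng.integers(700, 1301, size=n_ex - 1)
        length = int(exon_lens.sum() + intron_lens.sum())
        if length + 2 * margin >= config.genome_length:
            continue
        start = int(rng.integers(margin, config.genome_length - length - margin))
        if any(start - margin < e and s - margin < start + length for s, e in spans):
            continue
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_ex - 1:
                pos += int(intron_lens[i])
        u5 = int(rng.integers(20, max(21, int(exon_lens[0]) - 20)))
        u3 = int(rng.integers(20, max(21, int(exon_lens[-1]) - 20)))
        cds_lo = exons[0][0] + u5
        cds_hi = exons[-1][1] - u3
        cds = [
            (max(a, cds_lo), min(b, cds_hi))
            for a, b in exons
            if min(b, cds_hi) > max(a, cds_lo)
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene{len(genes) + 1:03d}"
        genes.append(GeneModel.from_exons_cds(gid, config.chrom_name, strand, exons, cds))
        spans.append((start, start + length))
    if len(genes) < config.n_genes:
        raise SimulationConfigError("infeasible packing: cannot place requested genes")
    return genes


# -- feature placement ------------------------------------------------------

def _plan_placements(rng, config: SimConfig, genes: list[GeneModel]) -> list[_Placement]:
    total = config.total_features
    classes = (
        ["complete"] * config.n_complete
        + ["solo_LTR"] * config.n_solo
        + ["fragment"] * config.n_fragment
    )
    n_intron = int(round(config.frac_intron * total))
    n_flank = int(round(config.frac_flank * total))
    contexts = ["intron"] * n_intron + ["flank_1kb"] * n_flank
    contexts += ["single_copy"] * (total - len(contexts))
    rng.shuffle(contexts)

    max_insert = config.element_length + config.tsd_length
    intron_slots = []
    for g in genes:
        for iv in g.introns:
            if iv[1] - iv[0] >= max_insert + 120:
                intron_slots.append((g, iv))
    flank_slots = [(g, side) for g in genes for side in ("up", "down")]
    rng.shuffle(intron_slots)
    rng.shuffle(flank_slots)

    chosen: list[int] = []

    def far_enough(p: int) -> bool:
        return all(abs(p - q) >= config.min_spacing for q in chosen)

    gene_bounds = [g.span for g in genes]
    placements: list[_Placement] = []
    for i, (cls, ctx) in enumerate(zip(classes, contexts)):
        placed = False
        for _ in range(400):
            if ctx == "intron":
                if not intron_slots:
                    raise SimulationConfigError(
                        "infeasible packing: not enough intron slots"
                    )
                g, iv = intron_slots[-1]
                lo, hi = iv[0] + 60, iv[1] - 60 - max_insert
                if hi <= lo:
                    intron_slots.pop()
                    continue
                p = int(rng.integers(lo, hi))
                if far_enough(p):
                    intron_slots.pop()
                    placed = True
                    break
                # slot conflicts with an earlier placement: try another one
                intron_slots.insert(0, intron_slots.pop())
            elif ctx == "flank_1kb":
                if not flank_slots:
                    raise SimulationConfigError(
                        "infeasible packing: not enough gene-flank slots"
                    )
                g, side = flank_slots[-1]
                s, e = g.span
                off = int(rng.integers(20, 1000 - max_insert))
                p = s - off - max_insert if side == "up" else e + off
                if 0 < p < config.genome_length - max_insert and far_enough(p):
                    flank_slots.pop()
                    placed = True
                    break
                flank_slots.insert(0, flank_slots.pop())
            else:
                p = int(rng.integers(1000, config.genome_length - max_insert - 1000))
                clear = all(
                    p + max_insert < s - 1200 or p > e + 1200 for s, e in gene_bounds
                )
                if clear and far_enough(p):
                    placed = True
                    break
        if not placed:
            raise SimulationConfigError("infeasible packing: no free insertion site")
        chosen.append(p)
        placements.append(
            _Placement(
                feature_id=f"planted{i + 1:04d}",
                cls=cls,
                context=ctx,
                bg_pos=p,
                insert="",
                element_offset=0,
                element_len=0,
                age=0.0,
                tsd=None,
            )
        )
    return placements


def _draw_age(rng, config: SimConfig, index: int) -> float:
    if config.ages_mya is not None:
        return float(config.ages_mya[index % len(config.ages_mya)])
    return float(rng.uniform(0.0, config.max_age_mya))


def _build_inserts(rng, config, placements, background, anc_ltr, anc_internal):
    tsdl = config.tsd_length
    completes = [pl for pl in placements if pl.cls == "complete"]
    nested_children = completes[len(completes) - config.n_nested :] if config.n_nested else []
    hosts = [pl for pl in completes if pl not in nested_children]
    age_index = 0
    for pl in placements:
        if pl.cls in ("complete", "solo_LTR", "fragment"):
            pl.age = _draw_age(rng, config, age_index)
            age_index += 1
    for pl in placements:
        tsd = background[pl.bg_pos : pl.bg_pos + tsdl]
        if pl.cls == "complete":
            ltr5, ltr3 = age_ltrs(anc_ltr, pl.age, config.rate_r, rng)
            internal = mutate_sequence(anc_internal, config.rate_r * pl.age * 1e6, rng)
            element = ltr5 + internal + ltr3
            pl.insert = element + tsd
            pl.element_offset = 0
            pl.element_len = len(element)
            pl.tsd = tsd
            pl.ltr_len = config.ltr_length
            pl.bg_pos += tsdl  # inserted after the duplicated target site
        elif pl.cls == "solo_LTR":
            solo = mutate_sequence(
                anc_ltr, config.rate_r * pl.age * 1e6, rng, exempt_termini=True
            )
            pl.insert = solo + tsd
            pl.element_offset = 0
            pl.element_len = len(solo)
            pl.tsd = tsd
            pl.ltr_len = config.ltr_length
            pl.bg_pos += tsdl
        else:  # fragment: a truncated copy, no TSD (boundaries eroded)
            ltr5, ltr3 = age_ltrs(anc_ltr, pl.age, config.rate_r, rng)
            internal = mutate_sequence(anc_internal, config.rate_r * pl.age * 1e6, rng)
            element = ltr5 + internal + ltr3
            frag_len = int(rng.integers(50, len(element)))
            off = int(rng.integers(0, len(element) - frag_len + 1))
            pl.insert = element[off : off + frag_len]
            pl.element_offset = 0
            pl.element_len = frag_len
            pl.tsd = None
    # nest requested children inside host internal regions (one level)
    host_pool = list(hosts)
    for child in nested_children:
        host = host_pool.pop(int(rng.integers(0, len(host_pool))))
        child.age = min(child.age, host.age)
        ltr5, ltr3 = age_ltrs(anc_ltr, child.age, config.rate_r, rng)
        internal = mutate_sequence(anc_internal, config.rate_r * child.age * 1e6, rng)
        element = ltr5 + internal + ltr3
        lo = host.element_offset + config.ltr_length + 10
        hi = host.element_offset + config.ltr_length + config.internal_length - 10 - tsdl
        q = int(rng.integers(lo, hi))
        tsd = host.insert[q : q + tsdl]
        host.insert = host.insert[: q + tsdl] + element + tsd + host.insert[q + tsdl :]
        host.element_len += len(element) + tsdl  # the nested block sits inside
        child.parent = host.feature_id
        child.context = host.context
        child.tsd = tsd
        child.element_len = len(element)
        child.ltr_len = config.ltr_length
        # child's genome position is derived from the host at assembly time
        child.bg_pos = -1
        child.element_offset = q + tsdl
        host.children.append(child)
    for child in nested_children:
        placements.remove(child)


# -- assembly and coordinate mapping ----------------------------------------

def _assemble(background, placements):
    ordered = sorted(placements, key=lambda pl: pl.bg_pos)
    parts = []
    cursor = 0
    offset = 0
    final_pos: dict[str, tuple[int, int, int | None]] = {}
    for pl in ordered:
        parts.append(background[cursor : pl.bg_pos])
        start = pl.bg_pos + offset
        el_start = start + pl.element_offset
        final_pos[pl.feature_id] = (el_start, el_start + pl.element_len, pl.ltr_len)
        for child in pl.children:
            c_start = start + child.element_offset
            final_pos[child.feature_id] = (
                c_start, c_start + child.element_len, child.ltr_len
            )
        parts.append(pl.insert)
        offset += len(pl.insert)
        cursor = pl.bg_pos
    parts.append(background[cursor:])
    return "".join(parts), final_pos


def _interval_mapper(placements):
    points = sorted((pl.bg_pos, len(pl.insert)) for pl in placements)

    def mapper(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        sa = sum(L for q, L in points if q <= a)
        sb = sum(L for q, L in points if q < b)
        return a + sa, b + sb

    return mapper


def _truth_table(config, placements, final_pos) -> pd.DataFrame:
    rows = []
    everything = []
    for pl in placements:
        everything.append(pl)
        everything.extend(pl.children)
    everything.sort(key=lambda pl: final_pos[pl.feature_id][0])
    for pl in everything:
        start, end, ltr_len = final_pos[pl.feature_id]
        has_ltrs = pl.cls in ("complete",) and ltr_len
        rows.append({
            "id": pl.feature_id,
            "chrom": config.chrom_name,
            "start": start,
            "end": end,
            "class": pl.cls,
            "true_age_mya": pl.age,
            "tsd": pl.tsd if pl.tsd else pd.NA,
            "context": pl.context,
            "parent": pl.parent if pl.parent else pd.NA,
            "ltr5_start": start if has_ltrs else pd.NA,
            "ltr5_end": start + ltr_len if has_ltrs else pd.NA,
            "ltr3_start": end - ltr_len if has_ltrs else pd.NA,
            "ltr3_end": end if has_ltrs else pd.NA,
            "motif_exempt": pl.cls in ("complete", "solo_LTR"),
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# -- small-RNA read emission ------------------------------------------------

def emit_srna_reads(
    truth: pd.DataFrame,
    genome: list[GenomeRecord],
    n_reads: int,
    lengths: tuple[int, ...] = (21, 23, 24),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Emit sRNA reads copied exactly from planted elements.

    Each read is an exact substring of a planted complete element or
    solo-LTR (forward or reverse-complement), reported in the RNA alphabet.
    Returns (reads, provenance) where provenance records the source element,
    offset and strand of every read.
    """
    rng = np.random.default_rng(seed)
    pool = truth[truth["class"].isin(["complete", "solo_LTR"])]
    if pool.empty:
        raise ValueError("no planted elements to draw sRNA reads from")
    shortest = int((pool["end"] - pool["start"]).min())
    if max(lengths) > shortest:
        raise ValueError(
            f"requested read length {max(lengths)} exceeds the shortest "
            f"element ({shortest} bp)"
        )
    by_name = {g.name: g for g in genome}
    reads = []
    prov = []
    for i in range(n_reads):
        row = pool.iloc[int(rng.integers(0, len(pool)))]
        length = int(rng.choice(lengths))
        off = int(rng.integers(0, int(row["end"]) - int(row["start"]) - length + 1))
        dna = by_name[row["chrom"]].sequence[
            int(row["start"]) + off : int(row["start"]) + off + length
        ]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = revcomp(dna)
        rid = f"sim-srna{i + 1:04d}"
        reads.append((rid, dna.replace("T", "U")))
        prov.append({
            "read_id": rid, "element_id": row["id"], "offset": off,
            "length": length, "strand": strand,
        })
    return reads, pd.DataFrame(prov)


def write_srna_fasta(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


# -- derived assemblies (insertion-polymorphism truth) ----------------------

def make_derived_assembly(
    records: list[GenomeRecord],
    truth: pd.DataFrame,
    excise_ids: list[str],
    tsd_len: int = 5,
) -> list[GenomeRecord]:
    """Copy an assembly with chosen planted elements excised to empty sites.

    For TSD-bearing features the element plus one TSD copy is removed,
    leaving the single-TSD pre-insertion allele; fragments are removed
    outright. Elements with nested children cannot be excised.
    """
    nested_parents = set(truth["parent"].dropna())
    cuts: dict[str, list[tuple[int, int]]] = {}
    for eid in excise_ids:
        row = truth[truth["id"] == eid]
        if row.empty:
            raise KeyError(f"unknown element {eid}")
        row = row.iloc[0]
        if row["id"] in nested_parents:
            raise ValueError(f"{eid} hosts a nested element; cannot excise")
        s, e = int(row["start"]), int(row["end"])
        if pd.notna(row["tsd"]):
            e += tsd_len  # drop the downstream TSD copy, keep the upstream one
        cuts.setdefault(str(row["chrom"]), []).append((s, e))
    out = []
    for rec in records:
        seq = rec.sequence
        for s, e in sorted(cuts.get(rec.name, []), reverse=True):
            seq = seq[:s] + seq[e:]
        out.append(GenomeRecord(rec.name, seq))
    return out


def simulate_to_dir(config: SimConfig, outdir, n_srna: int = 0) -> dict:
    """Run the generator and write genome.fa / genes.gff3 / truth.tsv
    (and srna.fa when requested) into ``outdir``."""
    from pathlib import Path

    from .io_formats import write_fasta, write_genes_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, genes, truth = simulate_genome(config)
    write_fasta(records, outdir / "genome.fa")
    write_genes_gff3(genes, outdir / "genes.gff3")
    write_truth(truth, outdir / "truth.tsv")
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
    }
    if n_srna:
        reads, prov = emit_srna_reads(truth, records, n_srna, seed=config.seed + 1)
        write_srna_fasta(reads, outdir / "srna.fa")
        prov.to_csv(outdir / "srna_provenance.tsv", sep="\t", index=False)
        paths["srna"] = outdir / "srna.fa"
    return paths
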
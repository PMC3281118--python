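"""Pipeline orchestration: detect and/or screen -> date -> context -> summary.

The config is a flat dict (usually loaded from YAML) naming the inputs and
overriding thresholds; every stage logs what it produced and all outputs
are written as plain-text tables so any number in the report traces back to
its inputs. Runs are deterministic given fixed inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from . import dating, genic_context, homology_screen, ltr_detect, srna_match
from .io_formats import read_fasta, read_gff3, write_elements
from .summary_stats import format_report, summarize_calls, summary_frame

log = logging.getLogger(__name__)

DEFAULTS = {
    "label": "assembly",
    "genome": None,           # FASTA, required
    "genes": None,            # GFF3, optional
    "library": None,          # FASTA, optional (enables homology screen)
    "library_spans": None,    # TSV companion for the library
    "srna": None,             # FASTA of small RNAs, optional
    "outdir": "smartltr_out",
    # detection thresholds
    "min_ltr": 50,
    "min_internal": 100,
    "max_element": 2000,
    "min_identity": 0.80,
    "tsd_len": 5,
    "require_motif": True,
    # screening thresholds
    "min_score": 250,
    "min_len": 50,
    # dating
    "rate": dating.DEFAULT_RATE,
    "model": "jukes_cantor",
    # context
    "flank": 1000,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(DEFAULTS, **user)
    if not cfg["genome"]:
        raise ValueError("config must name a genome FASTA")
    return cfg


def run_pipeline(config: dict) -> dict:
    """Execute the stages in dependency order; returns paths and tables.

    Stages: de novo detection always; homology screen when a library is
    configured; dating of complete calls; genic context when annotation is
    given (skipped and noted otherwise); sRNA mapping when reads are given;
    genome summary and plain-text report always.
    """
    cfg = dict(DEFAULTS, **config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report_lines = []
    outputs: dict = {"outdir": outdir}

    genomes = read_fasta(cfg["genome"])
    report_lines.append(
        f"genome: {cfg['genome']} ({len(genomes)} records, "
        f"{sum(g.length for g in genomes)} bp)"
    )

    calls = []
    for g in genomes:
        res = ltr_detect.detect_elements(
            g,
            min_ltr=cfg["min_ltr"],
            min_internal=cfg["min_internal"],
            max_element=cfg["max_element"],
            min_identity=cfg["min_identity"],
            tsd_len=cfg["tsd_len"],
            require_motif=cfg["require_motif"],
        )
        calls.extend(res.calls)
    report_lines.append(f"detect: {len(calls)} complete calls (de novo)")

    if cfg["library"]:
        library = homology_screen.load_library(cfg["library"], cfg["library_spans"])
        hits = homology_screen.screen_genome(
            genomes, library, min_score=cfg["min_score"], min_len=cfg["min_len"]
        )
        hom_calls = homology_screen.classify_hits(
            hits, genomes, library, tsd_len=cfg["tsd_len"]
        )
        # de novo calls take precedence at overlapping loci
        occupied = [(c.chrom, c.start, c.end) for c in calls]
        fresh = [
            h for h in hom_calls
            if not any(
                h.chrom == ch and h.start < e and s < h.end for ch, s, e in occupied
            )
        ]
        calls.extend(fresh)
        report_lines.append(
            f"screen: {len(hits)} hits -> {len(hom_calls)} classified calls, "
            f"{len(fresh)} new beyond de novo"
        )
    calls.sort(key=lambda c: (c.chrom, c.start))

    ages = dating.date_elements(calls, genomes, model=cfg["model"], r=cfg["rate"])
    ages_path = outdir / "ages.tsv"
    ages.to_csv(ages_path, sep="\t", index=False)
    outputs["ages"] = ages
    report_lines.append(f"date: {len(ages)} complete elements dated -> {ages_path.name}")

    calls_path = outdir / "calls.tsv"
    write_elements(calls, calls_path, fmt="tsv")
    write_elements(calls, outdir / "calls.gff3", fmt="gff3")
    outputs["calls"] = calls
    report_lines.append(f"calls: {len(calls)} rows -> {calls_path.name}")

    if cfg["genes"]:
        genes = read_gff3(cfg["genes"])
        contexts = [
            genic_context.classify_context(c, genes, flank=cfg["flank"]) for c in calls
        ]
        ctx_frame = genic_context.contexts_frame(contexts)
        ctx_frame.to_csv(outdir / "contexts.tsv", sep="\t", index=False)
        ctx_summary = genic_context.summarize_contexts(contexts, total=len(calls)) \
            if calls else None
        if ctx_summary is not None:
            ctx_summary.to_csv(outdir / "context_summary.tsv", sep="\t", index=False)
        outputs["contexts"] = contexts
        outputs["context_summary"] = ctx_summary
        report_lines.append(
            f"context: {len(contexts)} elements classified against "
            f"{len(genes)} gene models"
        )
    else:
        report_lines.append("context: skipped (no annotation configured)")

    if cfg["srna"]:
        reads = _read_srna_fasta(cfg["srna"])
        hits = srna_match.map_exact(reads, genomes)
        table, mean_sites = srna_match.summarize_srna(hits, calls)
        table.to_csv(outdir / "srna_sites.tsv", sep="\t", index=False)
        outputs["srna"] = table
        report_lines.append(
            f"srna: {len(reads)} reads, {len(hits)} exact sites, "
            f"mean {mean_sites:.1f} sites/sRNA"
        )

    summary = summarize_calls(calls, genomes, label=cfg["label"])
    summary_frame(summary).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    outputs["summary"] = summary
    report_lines.append("")
    report_lines.append(format_report(summary))
    report = "\n".join(report_lines) + "\n"
    (outdir / "report.txt").write_text(report)
    outputs["report"] = report
    for line in report_lines:
        log.info("%s", line)
    return outputs


def _read_srna_fasta(path) -> list[tuple[str, str]]:
    reads = []
    rid, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if rid is not None:
                    reads.append((rid, "".join(chunks)))
                rid, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if rid is not None:
        reads.append((rid, "".join(chunks)))
    return reads


def run_from_yaml(path) -> dict:
    return run_pipeline(load_config(path))
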
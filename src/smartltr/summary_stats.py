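"""Genome-level summary arithmetic: class ratios, densities, per-chromosome
counts. Rounding is half-up at the stated decimal places throughout."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io_formats import ElementCall, GenomeRecord


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (3.375 -> 3.4 at 1 dp), immune to binary-float
    banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def complete_solo_ratio(n_complete: int, n_solo: int) -> float | None:
    """Complete:solo-LTR ratio to one decimal ('x:1' form); None when no
    solo-LTRs were found."""
    if n_complete < 0 or n_solo < 0:
        raise ValueError("counts must be non-negative")
    if n_solo == 0:
        return None
    return round_half_up(n_complete / n_solo, 1)


def element_density(total_elements: int, genome_size_mb: float) -> float:
    """Elements per Mb, two decimals."""
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return round_half_up(total_elements / genome_size_mb, 2)


@dataclass
class GenomeSummary:
    label: str
    n_complete: int
    n_solo: int
    n_fragment: int
    ratio: float | None
    density_per_mb: float
    per_chromosome: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_complete + self.n_solo + self.n_fragment


def summarize_calls(
    calls: list[ElementCall], genomes: list[GenomeRecord], label: str = "assembly"
) -> GenomeSummary:
    n_c = sum(1 for c in calls if c.cls == "complete")
    n_s = sum(1 for c in calls if c.cls == "solo_LTR")
    n_f = sum(1 for c in calls if c.cls == "fragment")
    size_mb = sum(g.length for g in genomes) / 1e6
    per_chrom: dict[str, int] = {g.name: 0 for g in genomes}
    for c in calls:
        per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
    return GenomeSummary(
        label=label,
        n_complete=n_c,
        n_solo=n_s,
        n_fragment=n_f,
        ratio=complete_solo_ratio(n_c, n_s),
        density_per_mb=element_density(n_c + n_s + n_f, size_mb),
        per_chromosome=per_chrom,
    )


def summary_frame(summary: GenomeSummary) -> pd.DataFrame:
    return pd.DataFrame([{
        "assembly": summary.label,
        "complete": summary.n_complete,
        "solo_LTR": summary.n_solo,
        "fragment": summary.n_fragment,
        "total": summary.total,
        "complete_to_solo": summary.ratio if summary.ratio is not None else "NA",
        "elements_per_mb": summary.density_per_mb,
    }])


def format_report(summary: GenomeSummary) -> str:
    ratio = f"{summary.ratio}:1" if summary.ratio is not None else "NA"
    lines = [
        f"Assembly: {summary.label}",
        f"  complete elements : {summary.n_complete}",
        f"  solo-LTRs         : {summary.n_solo}",
        f"  fragments         : {summary.n_fragment}",
        f"  total             : {summary.total}",
        f"  complete:solo     : {ratio}",
        f"  density           : {summary.density_per_mb} elements/Mb",
        "  per chromosome    : "
        + ", ".join(f"{k}={v}" for k, v in sorted(summary.per_chromosome.items())),
    ]
    return "\n".join(lines)
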
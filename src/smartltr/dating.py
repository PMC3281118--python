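"""Insertion-time estimation from 5'/3' LTR divergence.

At insertion the two LTRs of a retrotransposon are identical; afterwards
each accumulates substitutions independently, so the divergence K between
them records twice the time since insertion: T = K / (2r), with r the
substitution rate per site per year (default 1.3e-8, the rice rate of
Ma & Bennetzen). K is the Jukes-Cantor-corrected proportion of mismatching
aligned sites by default; the raw p-distance is available for sensitivity
analysis. Gap columns of the global LTR alignment are excluded from the
aligned-site count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._align import global_divergence_counts
from .io_formats import ElementCall, GenomeRecord
from .summary_stats import round_half_up

DEFAULT_RATE = 1.3e-8  # substitutions / site / year
JC_SATURATION_P = 0.75
MIN_LTR_LEN = 20
SHORT_ALIGNMENT = 40


@dataclass
class AgeEstimate:
    element_id: str
    aligned_sites: int
    mismatches: int
    p_distance: float
    K: float | None
    model: str
    r: float
    T_years: float | None
    flags: str = ""

    @property
    def T_mya(self) -> float | None:
        """Insertion time in MYA, rounded to one decimal for reporting."""
        if self.T_years is None:
            return None
        return round_half_up(self.T_years / 1e6, 1)


def jukes_cantor(p: float) -> float:
    """JC69 distance: K = -(3/4) ln(1 - (4/3) p). Undefined for p >= 0.75."""
    if p >= JC_SATURATION_P:
        raise ValueError(f"p = {p} is saturated under Jukes-Cantor")
    return -0.75 * math.log1p(-4.0 / 3.0 * p)


def ltr_divergence(
    ltr5: str, ltr3: str, model: str = "jukes_cantor"
) -> tuple[float, float | None]:
    """Align the two LTRs globally and return (p, K).

    K is None when the JC correction is saturated (p >= 0.75).
    """
    if len(ltr5) < MIN_LTR_LEN or len(ltr3) < MIN_LTR_LEN:
        raise ValueError(f"LTR sequences must be >= {MIN_LTR_LEN} bp")
    if model not in ("raw_p", "jukes_cantor"):
        raise ValueError(f"unknown model {model!r}")
    sites, mismatches = global_divergence_counts(ltr5, ltr3)
    p = mismatches / sites
    if model == "raw_p":
        return p, p
    if p >= JC_SATURATION_P:
        return p, None
    return p, jukes_cantor(p)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """T = K / (2 r), in years."""
    if K < 0:
        raise ValueError("K must be non-negative")
    if r <= 0:
        raise ValueError("rate must be positive")
    return K / (2.0 * r)


def estimate_age(
    element_id: str,
    ltr5: str,
    ltr3: str,
    model: str = "jukes_cantor",
    r: float = DEFAULT_RATE,
) -> AgeEstimate:
    sites, mismatches = global_divergence_counts(ltr5, ltr3)
    p = mismatches / sites
    flags = []
    if sites < SHORT_ALIGNMENT:
        flags.append("short_alignment")
    if model == "raw_p":
        K: float | None = p
    elif p >= JC_SATURATION_P:
        K = None
        flags.append("saturated")
    else:
        K = jukes_cantor(p)
    T = insertion_time(K, r) if K is not None else None
    return AgeEstimate(
        element_id=element_id,
        aligned_sites=sites,
        mismatches=mismatches,
        p_distance=p,
        K=K,
        model=model,
        r=r,
        T_years=T,
        flags=",".join(flags),
    )


def date_elements(
    calls: list[ElementCall],
    genomes: list[GenomeRecord],
    model: str = "jukes_cantor",
    r: float = DEFAULT_RATE,
) -> pd.DataFrame:
    """Date every complete call with resolved LTR spans; returns a table.

    Columns: element id, p, K, model, T_years, T_mya, flags. Calls without
    both LTR spans (solo-LTRs, fragments) are skipped.
    """
    by_name = {g.name: g for g in genomes}
    rows = []
    for call in calls:
        if call.cls != "complete" or call.ltr5 is None or call.ltr3 is None:
            continue
        seq = by_name[call.chrom].sequence
        est = estimate_age(
            call.id,
            seq[call.ltr5[0] : call.ltr5[1]],
            seq[call.ltr3[0] : call.ltr3[1]],
            model=model,
            r=r,
        )
        call.age_mya = est.T_mya
        rows.append({
            "id": est.element_id,
            "aligned_sites": est.aligned_sites,
            "mismatches": est.mismatches,
            "p": est.p_distance,
            "K": est.K,
            "model": est.model,
            "T_years": est.T_years,
            "T_mya": est.T_mya,
            "flags": est.flags,
        })
    return pd.DataFrame(
        rows,
        columns=[
            "id", "aligned_sites", "mismatches", "p", "K", "model",
            "T_years", "T_mya", "flags",
        ],
    )
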
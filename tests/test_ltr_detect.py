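"""Structural detector: candidate scan vs brute-force oracle, validation rules."""

import numpy as np
import pytest

from smartltr.io_formats import GenomeRecord
from smartltr.ltr_detect import (
    CandidatePair,
    detect_elements,
    find_candidate_pairs,
    validate_candidates,
)
from smartltr.synthetic_data import SimConfig, simulate_genome
from smartltr._align import revcomp

from conftest import build_element, plant, rand_dna


# -- brute-force oracle -----------------------------------------------------

def oracle_candidate_pairs(seq, min_ltr=50, min_internal=100, max_element=2000,
                           min_identity=0.80):
    """Exhaustive all-pairs direct-repeat enumeration.

    Enumerates every (offset d, window [a,b)) with ungapped identity >=
    min_identity, L >= min_ltr, d - L >= min_internal, d + L <= max_element,
    then keeps windows not strictly contained in a valid window on the same
    offset. Independent of the implementation's prescreen/segment logic.
    """
    n = len(seq)
    found = []
    for d in range(min_ltr + min_internal, min(max_element - min_ltr, n - min_ltr) + 1):
        eq = [
            1 if seq[i] == seq[i + d] and seq[i] != "N" else 0
            for i in range(n - d)
        ]
        pref = np.concatenate(([0], np.cumsum(eq)))
        l_cap = min(d - min_internal, max_element - d)
        valid = []
        for a in range(len(eq) - min_ltr + 1):
            for L in range(min_ltr, min(l_cap, len(eq) - a) + 1):
                matches = int(pref[a + L] - pref[a])
                if matches / L >= min_identity:
                    valid.append((a, a + L, matches))
        maximal = [
            (a, b, m) for a, b, m in valid
            if not any(
                (a2 <= a and b <= b2 and (a2, b2) != (a, b)) for a2, b2, _ in valid
            )
        ]
        for a, b, m in maximal:
            found.append(((a, b), (a + d, b + d), m / (b - a)))
    return sorted(found)


def _as_tuples(pairs):
    return sorted((p.ltr5_span, p.ltr3_span, p.repeat_identity) for p in pairs)


@pytest.mark.parametrize("case", ["random", "identical_pair", "diverged_pair"])
def test_candidate_scan_equals_bruteforce_oracle(case, rng):
    if case == "random":
        seq = rand_dna(rng, 400)
    elif case == "identical_pair":
        ltr = rand_dna(rng, 60)
        seq = rand_dna(rng, 60) + ltr + rand_dna(rng, 150) + ltr + rand_dna(rng, 70)
    else:
        ltr = rand_dna(rng, 70)
        ltr2 = list(ltr)
        for i in rng.choice(70, size=7, replace=False):
            ltr2[i] = "ACGT"[(("ACGT".index(ltr2[i])) + 1) % 4]
        seq = rand_dna(rng, 40) + ltr + rand_dna(rng, 120) + "".join(ltr2) + rand_dna(rng, 60)
    impl = find_candidate_pairs(GenomeRecord("t", seq), resolve_overlaps=False)
    assert _as_tuples(impl) == oracle_candidate_pairs(seq)


def test_planted_292bp_element_detected_exactly(rng):
    """An element of two identical 85-bp repeats around a 122-bp internal
    region is recovered as a single candidate spanning 292 bp."""
    element, ltr, internal = build_element(rng)
    bg = rand_dna(rng, 4000)
    seq, start, end = plant(bg, 2000, element)
    pairs = find_candidate_pairs(GenomeRecord("t", seq))
    assert len(pairs) == 1
    res = validate_candidates(pairs, GenomeRecord("t", seq))
    assert len(res.calls) == 1
    call = res.calls[0]
    assert (call.start, call.end) == (start, end)
    assert call.end - call.start == 292
    assert call.ltr5[1] - call.ltr5[0] == 85
    assert call.tsd == "GACTC"


def test_null_sequence_yields_nothing(rng):
    seq = rand_dna(rng, 10_000)
    assert find_candidate_pairs(GenomeRecord("n", seq)) == []


def test_short_sequence_returns_empty():
    assert find_candidate_pairs(GenomeRecord("s", "ACGT" * 10)) == []


def test_revcomp_symmetry(rng):
    """Direct repeats are strand-symmetric: the reverse complement carries
    the same candidate set with mirrored coordinates."""
    element, _, _ = build_element(rng)
    seq, _, _ = plant(rand_dna(rng, 3000), 1500, element)
    n = len(seq)
    fwd = find_candidate_pairs(GenomeRecord("f", seq), resolve_overlaps=False)
    rev = find_candidate_pairs(GenomeRecord("r", revcomp(seq)), resolve_overlaps=False)
    mirrored = sorted(
        ((n - p.ltr3_span[1], n - p.ltr3_span[0]),
         (n - p.ltr5_span[1], n - p.ltr5_span[0]),
         p.repeat_identity)
        for p in rev
    )
    assert _as_tuples(fwd) == mirrored


def test_n_rich_candidates_dropped(rng):
    ltr = "TGT" + rand_dna(rng, 79) + "ACA"
    element = ltr + "N" * 122 + ltr
    seq, _, _ = plant(rand_dna(rng, 2000), 1000, element)
    assert find_candidate_pairs(GenomeRecord("t", seq)) == []
    relaxed = find_candidate_pairs(GenomeRecord("t", seq), max_n_fraction=0.5)
    assert len(relaxed) == 1


# -- validation -------------------------------------------------------------

def test_tsd_verification(rng):
    element, _, _ = build_element(rng)
    bg = rand_dna(rng, 2000)
    seq, start, end = plant(bg, 1000, element, tsd="GACTC")
    g = GenomeRecord("t", seq)
    res = detect_elements(g)
    assert len(res.calls) == 1 and res.calls[0].tsd == "GACTC"

    # one mismatch in the downstream copy: rejected under the exact policy
    broken = seq[:end] + "GACTA" + seq[end + 5 :]
    res2 = detect_elements(GenomeRecord("t", broken))
    assert res2.calls == []
    assert [reason for _, reason in res2.rejected] == ["tsd_mismatch"]

    # but accepted when one mismatch is allowed
    res3 = detect_elements(GenomeRecord("t", broken), tsd_max_mismatch=1)
    assert len(res3.calls) == 1


def test_motif_requirement_flag(rng):
    """An element starting TGA fails with require_motif, passes without."""
    element, ltr, internal = build_element(rng)
    element = "TGA" + element[3:-3] + "TCA"  # break both termini
    seq, start, end = plant(rand_dna(rng, 1200), 600, element)
    g = GenomeRecord("t", seq)
    pair = CandidatePair("t", (start, start + 85), (end - 85, end), 1.0)
    with_motif = validate_candidates([pair], g, require_motif=True)
    assert with_motif.calls == []
    assert with_motif.rejected[0][1] == "motif"
    without = validate_candidates([pair], g, require_motif=False)
    assert len(without.calls) == 1 and without.calls[0].tsd == "GACTC"


def test_contig_edge_marked_unresolved(rng):
    element, _, _ = build_element(rng)
    seq = element + rand_dna(rng, 500)  # no upstream flank at all
    g = GenomeRecord("t", seq)
    pair = CandidatePair("t", (0, 85), (207, 292), 1.0)
    res = validate_candidates([pair], g)
    assert res.calls == []
    assert res.rejected[0][1] == "edge_unresolved"


# -- recall / precision on the generator ------------------------------------

def test_recall_in_supported_age_range():
    """>= 95% of planted complete elements recovered where the LTR-pair
    identity stays above the 0.80 scan floor (ages <= 7.5 MYA)."""
    hit = total = 0
    for seed in (101, 102):
        cfg = SimConfig(max_age_mya=7.5, seed=seed)
        records, _, truth = simulate_genome(cfg)
        res = detect_elements(records[0])
        called = {(c.start, c.end) for c in res.calls}
        planted = truth[truth["class"] == "complete"]
        total += len(planted)
        hit += sum(
            (int(r.start), int(r.end)) in called for _, r in planted.iterrows()
        )
    assert total >= 40
    assert hit / total >= 0.95


def test_false_positive_rate_on_null_genomes():
    """<= 1 complete call per Mb on element-free random sequence."""
    fp = 0
    mb = 5
    for seed in range(mb):
        rng = np.random.default_rng(7_000 + seed)
        g = GenomeRecord(f"null{seed}", rand_dna(rng, 1_000_000))
        fp += len(detect_elements(g).calls)
    assert fp / mb <= 1.0
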
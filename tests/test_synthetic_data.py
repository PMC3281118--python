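"""Generator contracts: structure of planted elements, determinism, ageing."""

import numpy as np
import pytest

from smartltr.dating import jukes_cantor
from smartltr.srna_match import map_exact
from smartltr.synthetic_data import (
    SimConfig,
    SimulationConfigError,
    age_ltrs,
    emit_srna_reads,
    simulate_genome,
    simulate_to_dir,
)

from conftest import rand_dna


def test_truth_row_count_conservation():
    cfg = SimConfig(genome_length=200_000, n_complete=10, n_solo=3, n_fragment=5,
                    n_genes=6, seed=1)
    _, _, truth = simulate_genome(cfg)
    assert len(truth) == 18
    assert truth["class"].value_counts().to_dict() == {
        "complete": 10, "fragment": 5, "solo_LTR": 3
    }
    assert truth["id"].is_unique


def test_age_zero_gives_identical_ltrs(young_sim):
    _, (records, _, truth) = young_sim
    seq = records[0].sequence
    for _, row in truth[truth["class"] == "complete"].iterrows():
        s, e = int(row.start), int(row.end)
        ltr5 = seq[int(row.ltr5_start) : int(row.ltr5_end)]
        ltr3 = seq[int(row.ltr3_start) : int(row.ltr3_end)]
        assert ltr5 == ltr3
        assert seq[s : s + 3] == "TGT" and seq[e - 3 : e] == "ACA"


def test_planted_elements_have_duplicated_tsds(small_sim):
    _, (records, _, truth) = small_sim
    seq = records[0].sequence
    with_tsd = truth[truth["tsd"].notna() & truth["parent"].isna()]
    assert len(with_tsd) > 0
    for _, row in with_tsd.iterrows():
        s, e = int(row.start), int(row.end)
        assert seq[s - 5 : s] == row.tsd
        assert seq[e : e + 5] == row.tsd


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimConfig(genome_length=80_000, n_complete=4, n_solo=1, n_fragment=2,
                    n_genes=4, seed=9)
    p1 = simulate_to_dir(cfg, tmp_path / "a", n_srna=5)
    p2 = simulate_to_dir(cfg, tmp_path / "b", n_srna=5)
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes()


def test_infeasible_packing_raises_before_output():
    cfg = SimConfig(genome_length=5_000, n_complete=50, n_solo=0, n_fragment=0,
                    n_genes=0, seed=0)
    with pytest.raises(SimulationConfigError, match="packing"):
        simulate_genome(cfg)


def test_truth_contexts_match_emitted_annotation(small_sim):
    _, (_, genes, truth) = small_sim
    for _, row in truth.iterrows():
        s, e = int(row.start), int(row.end)
        if row.context == "intron":
            assert any(
                a <= s and e <= b for g in genes for a, b in g.introns
            ), row.id
        elif row.context == "flank_1kb":
            assert any(
                0 < min(abs(s - g.span[1]), abs(g.span[0] - e)) <= 1000
                for g in genes
            ), row.id
        elif row.context == "single_copy":
            assert all(
                e <= g.span[0] - 1000 or s >= g.span[1] + 1000 for g in genes
            ), row.id


def test_nested_element_recorded_and_structured():
    cfg = SimConfig(genome_length=200_000, n_complete=6, n_solo=0, n_fragment=0,
                    n_genes=4, n_nested=1, seed=21)
    records, _, truth = simulate_genome(cfg)
    seq = records[0].sequence
    child = truth[truth["parent"].notna()]
    assert len(child) == 1
    child = child.iloc[0]
    host = truth[truth["id"] == child["parent"]].iloc[0]
    assert host["start"] < child["start"] < child["end"] < host["end"]
    s, e = int(child.start), int(child.end)
    assert seq[s : s + 3] == "TGT" and seq[e - 3 : e] == "ACA"
    assert seq[s - 5 : s] == child.tsd == seq[e : e + 5]


# -- LTR ageing -------------------------------------------------------------

def test_age_zero_returns_input(rng):
    ltr = "TGT" + rand_dna(rng, 79) + "ACA"
    l5, l3 = age_ltrs(ltr, 0.0, 1.3e-8, seed=5)
    assert l5 == ltr and l3 == ltr


def test_aged_ltrs_keep_terminal_motifs(rng):
    ltr = "TGT" + rand_dna(rng, 79) + "ACA"
    l5, l3 = age_ltrs(ltr, 10.0, 1.3e-8, seed=6)
    for l in (l5, l3):
        assert l.startswith("TGT") and l.endswith("ACA")
    assert l5 != l3  # 10 MY of divergence essentially never leaves them equal


def test_mean_jc_divergence_matches_closed_form(rng):
    """Monte-Carlo oracle: mean JC-corrected divergence over replicate pairs
    aged to 5 MYA must sit within 3 SE of the closed form 2*r*T = 0.13."""
    ltr = "TGT" + rand_dna(rng, 79) + "ACA"
    target = 2 * 1.3e-8 * 5.0e6
    ks = []
    for i in range(2000):
        l5, l3 = age_ltrs(ltr, 5.0, 1.3e-8, seed=100_000 + i)
        mismatches = sum(a != b for a, b in zip(l5, l3))
        ks.append(jukes_cantor(mismatches / len(ltr)))
    ks = np.asarray(ks)
    se = ks.std(ddof=1) / np.sqrt(len(ks))
    assert abs(ks.mean() - target) < 3 * se


def test_divergence_beyond_jc_cap_refused(rng):
    # closed form: 2 * 1.3e-8 * 36.9e6 = 0.959 per site, beyond the 0.70 cap
    assert 2 * 1.3e-8 * 36.9e6 == pytest.approx(0.9594)
    ltr = "TGT" + rand_dna(rng, 79) + "ACA"
    with pytest.raises(SimulationConfigError, match="cap"):
        age_ltrs(ltr, 36.9, 1.3e-8, seed=1)
    with pytest.raises(SimulationConfigError):
        SimConfig(ages_mya=[36.9]).validate()


# -- sRNA emission ----------------------------------------------------------

def test_srna_reads_exact_substrings(small_sim):
    _, (records, _, truth) = small_sim
    reads, prov = emit_srna_reads(truth, records, n_reads=10, seed=4)
    assert len(reads) == 10 and len(prov) == 10
    genome_fwd = records[0].sequence
    for rid, rna in reads:
        assert set(rna) <= set("ACGU")
        assert len(rna) in (21, 23, 24)
        dna = rna.replace("U", "T")
        rc = dna.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert dna in genome_fwd or rc in genome_fwd


def test_srna_read_length_exceeding_element_rejected(small_sim):
    _, (records, _, truth) = small_sim
    with pytest.raises(ValueError, match="length"):
        emit_srna_reads(truth, records, n_reads=1, lengths=(500,), seed=0)


def test_read_from_multicopy_element_hits_every_locus(young_sim):
    """15 identical planted copies: a read drawn from one matches every
    locus -- once per element, or twice when it falls entirely inside the
    duplicated LTR (which every copy carries at both ends)."""
    cfg, (records, _, truth) = young_sim
    reads, prov = emit_srna_reads(truth, records, n_reads=8, seed=8)
    ltr, internal = cfg.ltr_length, cfg.internal_length
    internal_reads = 0
    for (rid, rna), (_, p) in zip(reads, prov.iterrows()):
        hits = map_exact([(rid, rna)], records)
        lo, hi = p.offset, p.offset + p.length
        in_ltr = hi <= ltr or lo >= ltr + internal
        if in_ltr:
            assert len(hits) == 30
        else:
            internal_reads += 1
            assert len(hits) == 15
    assert internal_reads > 0
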
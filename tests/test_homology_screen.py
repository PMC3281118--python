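"""Library screening: cutoff semantics, classification, synthetic accuracy."""

import numpy as np
import pytest

from smartltr.homology_screen import (
    LibraryElement,
    classify_hits,
    load_library,
    screen_genome,
)
from smartltr.io_formats import GenomeRecord, write_fasta
from smartltr.synthetic_data import SimConfig, simulate_genome
from smartltr._align import revcomp

from conftest import build_element, plant, rand_dna


@pytest.fixture()
def library(rng):
    element, ltr, internal = build_element(rng)
    return [LibraryElement("ref", element, (0, 85), (85, 207), (207, 292))]


def test_library_spans_must_tile():
    with pytest.raises(ValueError, match="tile"):
        LibraryElement("bad", "A" * 292, (0, 85), (85, 200), (207, 292))


def test_exact_self_match(library, rng):
    elem = library[0].sequence
    genome = [GenomeRecord("c", rand_dna(rng, 700) + elem + rand_dna(rng, 700))]
    hits = screen_genome(genome, library)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end) == (700, 700 + 292)
    assert h.identity == 1.0
    assert h.library_span == (0, 292)


def test_60bp_segment_retained_40bp_filtered(library, rng):
    seg60 = library[0].sequence[10:70]
    seg40 = library[0].sequence[10:50]
    g60 = [GenomeRecord("c", rand_dna(rng, 500) + seg60 + rand_dna(rng, 500))]
    g40 = [GenomeRecord("c", rand_dna(rng, 500) + seg40 + rand_dna(rng, 500))]
    hits60 = screen_genome(g60, library)
    assert len(hits60) == 1 and hits60[0].end - hits60[0].start == 60
    assert screen_genome(g40, library) == []


def test_reverse_strand_hit_found(library, rng):
    elem = library[0].sequence
    genome = [GenomeRecord("c", rand_dna(rng, 600) + revcomp(elem) + rand_dna(rng, 600))]
    hits = screen_genome(genome, library)
    assert len(hits) == 1 and hits[0].strand == "-"
    assert hits[0].library_span == (0, 292)


def test_raising_min_score_never_adds_hits(library, rng):
    # monotonicity of the score filter
    elem = library[0].sequence
    parts = [rand_dna(rng, 400), elem, rand_dna(rng, 400), elem[:80],
             rand_dna(rng, 400)]
    genome = [GenomeRecord("c", "".join(parts))]
    previous = None
    for cutoff in (100, 250, 500, 1000, 3000):
        n = len(screen_genome(genome, library, min_score=cutoff))
        if previous is not None:
            assert n <= previous
        previous = n


def test_classification_three_archetypes(library, rng):
    """Full element with TSDs -> complete; lone LTR with TSDs -> solo_LTR;
    internal-only segment -> fragment."""
    lib = library[0]
    bg = rand_dna(rng, 6000)
    seq, cs, ce = plant(bg, 1000, lib.sequence, tsd="GATTC")
    seq, ss, se = plant(seq, 3000, lib.sequence[0:85], tsd="ATTGC")
    internal_only = lib.sequence[85:207]
    seq = seq[:5000] + internal_only + seq[5000:]
    genome = [GenomeRecord("c", seq)]
    hits = screen_genome(genome, library)
    calls = classify_hits(hits, genome, library)
    assert len(calls) == len(hits)  # count conservation: one call per cluster
    by_class = {c.cls: c for c in calls}
    assert set(by_class) == {"complete", "solo_LTR", "fragment"}
    assert by_class["complete"].tsd == "GATTC"
    assert by_class["solo_LTR"].tsd == "ATTGC"
    assert by_class["solo_LTR"].end - by_class["solo_LTR"].start == 85
    assert by_class["fragment"].tsd is None


def test_solo_without_tsd_is_fragment(library, rng):
    lib = library[0]
    seq = rand_dna(rng, 2000) + lib.sequence[0:85] + rand_dna(rng, 2000)
    genome = [GenomeRecord("c", seq)]
    calls = classify_hits(screen_genome(genome, library), genome, library)
    assert [c.cls for c in calls] == ["fragment"]


def test_contig_edge_falls_back_to_fragment(library):
    genome = [GenomeRecord("c", library[0].sequence)]  # no flanks at all
    calls = classify_hits(screen_genome(genome, library), genome, library)
    assert len(calls) == 1
    assert calls[0].cls == "fragment" and "edge" in calls[0].flags


def test_library_roundtrip_via_files(tmp_path, library):
    write_fasta(
        [GenomeRecord(library[0].id, library[0].sequence)], tmp_path / "lib.fa"
    )
    (tmp_path / "spans.tsv").write_text("id\tltr5_end\tinternal_end\nref\t85\t207\n")
    lib = load_library(tmp_path / "lib.fa", tmp_path / "spans.tsv")
    assert lib[0].ltr5_span == (0, 85) and lib[0].ltr3_span == (207, 292)


def test_class_recovery_on_simulated_genome():
    """Planted class labels recovered with >= 95% accuracy at >= 85%
    copy-to-library identity (ages <= 6 MYA against the family ancestor)."""
    cfg = SimConfig(
        genome_length=250_000, n_complete=10, n_solo=6, n_fragment=8,
        n_genes=8, max_age_mya=6.0, seed=31,
    )
    records, _, truth = simulate_genome(cfg)
    anc = truth.attrs["ancestral_element"]
    library = [LibraryElement("anc", anc, (0, 85), (85, 207), (207, 292))]
    hits = screen_genome(records, library)
    calls = classify_hits(hits, records, library)
    correct = 0
    for _, row in truth.iterrows():
        overlapping = [
            c for c in calls
            if c.chrom == row.chrom and c.start < row.end and row.start < c.end
        ]
        if overlapping and overlapping[0].cls == row["class"]:
            correct += 1
    assert correct / len(truth) >= 0.95
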
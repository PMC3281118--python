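"""Summary arithmetic (ratios, densities) and end-to-end pipeline runs."""

import pytest
import yaml

from smartltr.io_formats import write_fasta, write_genes_gff3
from smartltr.pipeline import load_config, run_pipeline
from smartltr.summary_stats import (
    complete_solo_ratio,
    element_density,
    format_report,
    round_half_up,
    summarize_calls,
)
from smartltr.synthetic_data import (
    SimConfig,
    emit_srna_reads,
    simulate_genome,
    write_srna_fasta,
    write_truth,
)


def test_round_half_up_policy():
    assert round_half_up(3.375, 1) == 3.4
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(24.785714, 1) == 24.8
    assert round_half_up(52.67, 0) == 53


@pytest.mark.parametrize(
    "n_complete,n_solo,expected",
    [(27, 8, 3.4), (33, 7, 4.7), (347, 14, 24.8), (10, 0, None)],
)
def test_complete_solo_ratio(n_complete, n_solo, expected):
    assert complete_solo_ratio(n_complete, n_solo) == expected


@pytest.mark.parametrize(
    "total,size_mb,expected",
    [(262, 383, 0.68), (28, 28.5, 0.98), (0, 100, 0.0)],
)
def test_element_density(total, size_mb, expected):
    assert element_density(total, size_mb) == expected


def test_density_rejects_zero_size():
    with pytest.raises(ValueError):
        element_density(10, 0)


def test_summary_totals_and_report(small_sim):
    from smartltr.io_formats import ElementCall

    _, (records, _, truth) = small_sim
    calls = [
        ElementCall(id=r.id, chrom=r.chrom, start=int(r.start), end=int(r.end),
                    cls=r["class"])
        for _, r in truth.iterrows()
    ]
    summary = summarize_calls(calls, records, label="sim")
    assert summary.total == len(truth)
    assert sum(summary.per_chromosome.values()) == summary.total
    report = format_report(summary)
    assert str(summary.n_complete) in report and "elements/Mb" in report


# -- pipeline orchestration -------------------------------------------------

@pytest.fixture(scope="module")
def pipeline_inputs(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("pipein")
    cfg = SimConfig(
        genome_length=150_000, n_complete=8, n_solo=2, n_fragment=3,
        n_genes=8, max_age_mya=6.0, seed=23,
    )
    records, genes, truth = simulate_genome(cfg)
    write_fasta(records, tmp / "genome.fa")
    write_genes_gff3(genes, tmp / "genes.gff3")
    write_truth(truth, tmp / "truth.tsv")
    reads, _ = emit_srna_reads(truth, records, 6, seed=1)
    write_srna_fasta(reads, tmp / "srna.fa")
    anc = truth.attrs["ancestral_element"]
    write_fasta(
        [__import__("smartltr").GenomeRecord("anc", anc)], tmp / "lib.fa"
    )
    (tmp / "spans.tsv").write_text("id\tltr5_end\tinternal_end\nanc\t85\t207\n")
    return tmp, cfg, truth


def test_pipeline_end_to_end_recovers_truth(pipeline_inputs, tmp_path):
    tmp, cfg, truth = pipeline_inputs
    out = run_pipeline({
        "genome": str(tmp / "genome.fa"),
        "genes": str(tmp / "genes.gff3"),
        "library": str(tmp / "lib.fa"),
        "library_spans": str(tmp / "spans.tsv"),
        "srna": str(tmp / "srna.fa"),
        "outdir": str(tmp_path / "run1"),
        "label": "sim",
    })
    summary = out["summary"]
    n_true = int((truth["class"] == "complete").sum())
    assert summary.n_complete >= 0.9 * n_true
    for name in ("calls.tsv", "calls.gff3", "ages.tsv", "contexts.tsv",
                 "context_summary.tsv", "srna_sites.tsv", "summary.tsv",
                 "report.txt"):
        assert (tmp_path / "run1" / name).exists()
    assert "srna" in out["report"]


def test_pipeline_skips_context_without_annotation(pipeline_inputs, tmp_path):
    tmp, _, _ = pipeline_inputs
    out = run_pipeline({
        "genome": str(tmp / "genome.fa"),
        "outdir": str(tmp_path / "run2"),
    })
    assert "context: skipped" in out["report"]
    assert not (tmp_path / "run2" / "contexts.tsv").exists()


def test_pipeline_deterministic_report(pipeline_inputs, tmp_path):
    tmp, _, _ = pipeline_inputs
    cfg = {"genome": str(tmp / "genome.fa"), "genes": str(tmp / "genes.gff3")}
    r1 = run_pipeline({**cfg, "outdir": str(tmp_path / "d1")})
    r2 = run_pipeline({**cfg, "outdir": str(tmp_path / "d2")})
    assert r1["report"] == r2["report"]
    assert (tmp_path / "d1" / "calls.tsv").read_bytes() == (
        tmp_path / "d2" / "calls.tsv"
    ).read_bytes()


def test_yaml_config_validation(tmp_path, pipeline_inputs):
    tmp, _, _ = pipeline_inputs
    good = tmp_path / "ok.yaml"
    good.write_text(yaml.safe_dump({"genome": str(tmp / "genome.fa")}))
    assert load_config(good)["genome"].endswith("genome.fa")
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump({"genome": "g.fa", "bogus_key": 1}))
    with pytest.raises(ValueError, match="unknown config keys"):
        load_config(bad)
    missing = tmp_path / "missing.yaml"
    missing.write_text(yaml.safe_dump({"label": "x"}))
    with pytest.raises(ValueError, match="genome"):
        load_config(missing)
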
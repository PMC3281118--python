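# smartltr

Discovery, classification, dating and genic-context analysis of **miniature
LTR retrotransposons** — the smallest known class of LTR elements
(~292 bp, with ~85-bp long terminal repeats), found across grass genomes
and, unlike most LTR retrotransposons, concentrated in and near genes.

The package is for genome annotators and transposon biologists who need to
find these elements in an assembly, decide whether each locus is a complete
element, a solo-LTR or a fragment, estimate when each copy inserted, and
relate copies to gene models, to a second assembly, and to small-RNA data.

## What it computes

* **Structural detection** — scan a sequence for pairs of ungapped direct
  repeats (≥50 bp, ≥80% identity, ≥100 bp apart, total span ≤2 kb), then
  validate the hallmarks of an LTR retrotransposon insertion: 5′TGT…ACA3′
  termini and a 5-bp target-site duplication (TSD) on both flanks.
* **Homology screening** — local alignment of a reference element library
  against a genome (score ≥250, hit length ≥50 bp), with clusters
  classified as complete / solo-LTR / fragment from LTR-region coverage and
  flanking TSDs.
* **Insertion dating** — the two LTRs of an element are identical at
  insertion and diverge independently afterwards, so

  *T* = *K* / (2 *r*),

  where *K* is the Jukes–Cantor-corrected divergence between the aligned
  LTRs (*K* = −¾ ln(1 − 4*p*/3), gap columns excluded) and
  *r* = 1.3×10⁻⁸ substitutions · site⁻¹ · year⁻¹.
* **Genic context** — one category per element (coding exon > UTR > intron
  by largest overlap, then within-1-kb flank, repeat-masked/multi-copy
  "other", or single-copy), with Table-style count/percentage summaries.
* **Insertion polymorphisms** — anchor an element's 200-bp flanks in a
  second assembly; a junction carrying exactly one TSD copy is the
  pre-insertion (empty) allele, proving a new insertion.
* **sRNA mapping** — exact-match (100% identity) mapping of 18–30-nt small
  RNAs to both strands, split into element-derived and other loci.
* **Phylogeny** — pairwise p-distance / Jukes–Cantor matrices and a
  Saitou–Nei neighbor-joining tree with newick output.
* **Synthetic genomes** — a first-class generator that plants complete
  elements (LTRs aged under a per-site Poisson Jukes–Cantor process),
  solo-LTRs, fragments and nested copies into background DNA with gene
  models, emitting a truth table so every stage can be scored.

## Worked example

```python
from smartltr import SimConfig, detect_elements, simulate_genome
from smartltr.dating import date_elements

config = SimConfig(genome_length=200_000, n_complete=10, n_solo=3,
                   n_fragment=4, n_genes=8, max_age_mya=6.0, seed=7)
records, genes, truth = simulate_genome(config)
result = detect_elements(records[0])
print(len(result.calls))          # 10 - every planted element recovered
ages = date_elements(result.calls, records)
print(ages[["id", "p", "K", "T_mya"]].head(3))
```

Running `python examples/01_simulate_and_detect.py` prints:

```
planted complete elements : 10
structural calls          : 10
recovered exactly         : 10
  smart_chr1_0001  [6597, 6889)  TSD=GGGTC  LTR identity=0.841
```

meaning the detector found all ten planted elements at exact boundaries,
each confirmed by its duplicated 5-bp target site; the identity column is
the divergence of the element's two LTRs, the raw material for dating.
The other scripts in `examples/` walk through dating, genic context,
polymorphism calling, sRNA mapping and tree building the same way.

A thin CLI mirrors the library (`smartltr sim|detect|screen|date|context|
compare|srna|tree|run`); `smartltr run --config pipeline.yaml` executes
the stages in dependency order and writes TSV/GFF3 outputs plus a
plain-text report.

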
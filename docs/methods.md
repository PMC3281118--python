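# Methods

## The element model

The package targets miniature LTR retrotransposons: non-autonomous
elements of roughly 292 bp consisting of two ~85-bp long terminal repeats
(LTRs) flanking a ~122-bp internal region. A complete element starts TGT
and ends ACA (the canonical LTR termini) and is flanked by a 5-bp
target-site duplication (TSD) created at insertion. A solo-LTR is a single
LTR with TSDs, the relic of intra-element recombination; a fragment is any
truncated remnant. These three classes, and the quantities derived from
them (complete:solo ratio, density per Mb, insertion ages, genic context),
are the package's subject matter.

## Structural detection

`ltr_detect.find_candidate_pairs` searches one sequence for ungapped
direct-repeat pairs. A candidate is an offset *d* and window [a, a+L) such
that seq[a:a+L] and seq[a+d:a+d+L] match at ≥ `min_identity` with
L ≥ `min_ltr` (50 bp), internal separation d−L ≥ `min_internal` (100 bp)
and total span d+L ≤ `max_element` (2000 bp). For each offset the match
vector is computed with numpy and prescreened by a sliding `min_ltr`
window at threshold 2t−1 (t = `min_identity`). This prescreen is
*complete*: any valid window of identity ≥ t contains a `min_ltr`
sub-window of identity ≥ 2t−1 (partition the window into `min_ltr` blocks
and bound the best block), so no candidate can be missed — the design
trades the usual k-mer seeding (whose exactness guarantee collapses for
short diverged repeats) for a scan whose cost is linear per offset.
Qualifying neighbourhoods are enumerated exactly; windows strictly
contained in another valid window on the same offset are dropped
(maximality), and overlapping candidates are resolved greedily by
identity × LTR length, ties to the leftmost start.

No gapped refinement is performed: the repeats the pipeline models (and
the generator plants) diverge by substitutions only, and the dating
formula downstream likewise assumes substitutions. Real elements with
indel-riddled LTRs would be recovered only if an ungapped sub-window still
clears the identity floor.

`validate_candidates` promotes a repeat pair to a complete call iff the
5 bases immediately upstream equal the 5 bases immediately downstream
(exact by default; length 4–6 and ≤1 mismatch configurable) and the
element begins TGT / ends ACA. Because a maximal repeat window can drift
into flanking sequence by up to ≈ t/(1−t) mismatch-buffered bases (and up
to the per-offset length cap) while staying above threshold, boundaries
are refined by searching for a TGT start and ACA end within 40 bp of the
window edges and accepting the pair whose flanks duplicate. The joint
motif+TSD requirement makes a spurious refinement essentially impossible
(~4⁻¹¹ per offset pair). Failure reasons (`motif`, `tsd_mismatch`,
`edge_unresolved`) are best-effort diagnostics, attributed by whether a
near-miss duplication existed at motif-consistent boundaries.

**Detection envelope.** With t = 0.80 the scan is reliable while the
LTR-pair identity stays above the floor. Expected pair divergence is
2rT: at T = 7.5 MYA expected identity is ≈0.83 and measured recall on
simulated genomes is ≥0.98; at T → 10 MYA expected identity crosses 0.80
and recall for the oldest elements decays (overall ≈0.92 for ages uniform
on [0,10] MYA). This is a property of the identity threshold, not of the
implementation; older copies are recovered by the homology screen instead.

## Homology screening

`homology_screen.screen_genome` seeds exact 11-mers between genome and
library element (both strands), bands seeds by diagonal and runs an
optimal local alignment per banded window (match +10, mismatch −10, gap
open −50, extend −10), keeping hits with score ≥250 and length ≥50 bp.
With these magnitudes an exact match longer than 25 bp clears the score
cutoff, so the length filter is the binding constraint for short hits —
matching the intended cutoff semantics of repeat-masking screens, whose
matrices score roughly +10 per matched base. Overlapping hits from
different library members keep the best-scoring representative.

`classify_hits` clusters hits within 50 bp (same chromosome and strand,
tolerant of nested interruptions) and classifies each cluster: complete if
both library LTR regions are covered ≥80% and a TSD is verified on the
genomic flanks (searched within ±3 bp of the cluster edges, nearest offset
first, since local alignments can miss the exact edge); solo-LTR if
exactly one LTR region is covered, internal coverage is <20%, the span is
0.9–1.05× the library LTR length, and TSDs verify; otherwise fragment.
Contig-edge clusters fall back to fragment with an `edge` flag.

## Insertion dating

`dating.ltr_divergence` globally aligns the two LTRs (match +1, mismatch
−1, gap −2), excludes gap columns, and computes p = mismatches/aligned
sites. The default distance is Jukes–Cantor, K = −¾ ln(1 − 4p/3),
undefined (flagged `saturated`) at p ≥ 0.75; raw p is available for
sensitivity. `insertion_time` applies T = K/(2r) with r = 1.3×10⁻⁸
substitutions·site⁻¹·year⁻¹, the rice synonymous rate conventionally used
for grass retroelement dating. Reported ages are rounded half-up to 0.1
MYA; alignments shorter than 40 sites carry a `short_alignment` flag.
With ~85 aligned sites the binomial noise on p dominates: the standard
deviation of a single estimate is ≈0.9 MYA at T = 5 MYA, so individual
ages are indicative while means over many elements are accurate (the
suite verifies mean recovery within 10% up to 15 MYA).

## Genic context

One category per element. Within a gene body the feature type (coding
exon, UTR, intron) with the largest overlap wins, ties to the higher
precedence type (exon > utr > intron); UTRs are always derived from the
exon/CDS set difference rather than trusted from annotation lines, and
"exon" means coding exon, as distinct UTR rows in the summary imply.
Elements without gene-body overlap are `flank_1kb` when a boundary lies
within 1 kb of a gene span (strand-agnostic, either side, measured from
the element boundary), `other` when they overlap a user-supplied repeat
mask or are flagged multi-copy (self-derived copy-number estimation is out
of scope), else `single_copy`. Percentages are rounded half-up to one
decimal; the combined in-or-near-genes percentage to the nearest integer.

## Insertion polymorphisms

For an element in a carrier assembly, the 200-bp flanks (the left one
ending with the upstream TSD copy, the right one starting with the
downstream copy) are anchored in the other assembly by local alignment,
requiring ≥90% identity over ≥90% of the flank. Exactly one acceptable
anchor per flank is required; two or more is `unresolved/ambiguous_flanks`
(multi-mapping flanks are surfaced, never silently dropped). With both
anchors on one sequence, the gap between the projected flank termini
decides the call: an element-length homologous insert (length within 20%,
identity ≥0.7) is `shared`; anchors abutting within −5…0.1×element-length
with exactly one TSD copy at the junction is `new_insertion` (the
pre-insertion allele carries one TSD; insertion duplicates it); anything
else is `unresolved` with a reason.

## sRNA mapping and phylogeny

sRNA reads (RNA or DNA alphabet, 18–30 nt) are uppercased, U→T converted
and matched exactly against both strands with an exhaustive substring
scan; every occurrence is reported, and a palindromic read matching both
strands at one locus counts once. Summaries split sites by element
overlap (transposon + other = total per read) and report the mean sites
per read.

Distances for trees come from all-pairs global alignment under p-distance
(default) or Jukes–Cantor, saturated JC pairs clamped to 2.0 and flagged.
`neighbor_joining` is a from-scratch Saitou–Nei implementation: Q-matrix
minimisation with ties broken on the lexicographically smallest pair of
cluster labels (a cluster labelled by its smallest leaf), negative branch
lengths clamped to zero with the deficit moved to the sister branch, and
a trifurcating root emitted for the final three clusters. NJ is consistent
on additive matrices (verified to 1e-9 in the suite and cross-checked
against dendropy's implementation). The maximum-composite-likelihood
distance of some desktop phylogeny suites is deliberately not reproduced;
p/JC distances are standard and sufficient for family-structure trees of
~300-bp elements. Bootstrap support (column resampling, default 100
replicates) is offered for pre-aligned, equal-length input only: the
all-pairs route yields no common column set to resample, so unaligned
elements must be aligned externally first. No automated subfamily caller
is provided — subfamily cutting criteria are a user decision.

## The synthetic-data generator

`synthetic_data.simulate_genome` is the package's benchmark instrument,
not a test fixture. It emulates: background DNA of tunable GC (default
0.44, grass-like) and length (default 300 kb); planted complete elements
with the full anatomy above; solo-LTRs with TSDs; fragments (uniform
sub-spans ≥50 bp of an aged element, no TSD — boundary erosion is why
fragments exist); optional one-level nesting (an element inside a host's
internal region, with its own TSD cut from host sequence); gene models
with 3–6 exons, 700–1300-bp introns and CDS-derived UTRs; and sRNA reads
copied exactly from planted elements (lengths 21/23/24 nt, both strands,
RNA alphabet). Contexts follow the configured mix (defaults 28% intronic,
20% within 1 kb of genes, rest intergenic — the rice proportions) and the
truth table records span, class, age, TSD, context and nesting for every
feature, with the family consensus exposed in `truth.attrs` for use as a
screening library.

LTR ageing is a per-site Poisson substitution process with equal-rate
(Jukes–Cantor) replacement, so multiple hits can revert and the JC
correction is the exact inverse of the generating process. Each copy
receives expectation r·T substitutions per site; the terminal 3-bp motifs
are exempt (a decayed motif would make detector-recall targets measure
motif erosion, not detector correctness) and the remaining sites are
up-weighted by L/(L−6) so the whole-LTR expected divergence is exactly
2rT — keeping both the Monte-Carlo calibration oracle and the dating
estimator unbiased. Ages beyond an expected divergence of 0.70/site
(≈26.9 MYA at the default rate) are refused: the JC logarithm approaches
its singularity and simulated ages there would be unrecoverable by
construction. Elements are placed ≥2.5 kb apart by default so that LTRs
of *different* planted copies cannot pair within the 2-kb element span
during detection; nested configurations deliberately violate this and are
validated structurally rather than through detection recall.

What the generator does **not** emulate — indels and rearrangements
within elements, motif decay, solo-LTR formation as a recombination
process (solo-LTRs are planted, not derived), segmental duplications, or
assembly gaps beyond optional N content. Passing recovery tests therefore
demonstrates correctness of the algorithms under the substitution-only
model, not performance on real assemblies, where indels and boundary
ambiguity will reduce recall and blur ages.

## Numerical and reporting conventions

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
inclusive convention exists only at file boundaries, BED stays 0-based.
All rounding is decimal round-half-up at the stated precision (ratios one
decimal, densities two, percentages one); with this single rule a
347:14 ratio prints as 24.8, whereas truncation would print 24.7 — one
rule is kept rather than matching any one printed table. Candidate spans
containing >10% N are dropped at detection (configurable); N never counts
as a match. Identity comparisons use plain floating-point `matches/L ≥ t`
(IEEE-deterministic and mirrored by the test oracles). All randomness
flows through numpy Generators seeded from a single integer; identical
config and seed give byte-identical FASTA/GFF3/TSV outputs.

## Problem sizes used by the suite

The test suite runs at desk scale, chosen as representative rather than
exhaustive: detector-oracle instances of 300–500 bp; recall measured on
300-kb genomes with 20 planted elements per seed (5 seeds, 100 elements);
null false-positive rate on 5 seeded 1-Mb element-free genomes; sRNA
oracle equivalence on a 1-Mb simulated genome; dating recovery on 200
replicate pairs per age at 5/10/15 MYA; polymorphism recovery with 4
excisions among 10 elements. The full suite completes in about a minute
on one CPU.

## Known limitations

* The detector's identity floor bounds the de novo age horizon (~9 MYA at
  defaults); older copies must come from the homology screen, whose own
  horizon is the score cutoff against the library.
* Dating assumes no gene conversion between LTRs and a clock-like rate;
  both assumptions bias real ages low and are not modelled.
* `other` genic context requires a user-supplied repeat mask; without one,
  multi-copy regions classify as single-copy.
* Polymorphism calling is locus-by-locus anchoring, not whole-genome
  alignment; rearranged flanks resolve as `unresolved`.
* Exact sRNA matching only; mismatch-tolerant mapping and abundance
  normalisation are out of scope.
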
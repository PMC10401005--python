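# Methods

This note documents the models, rules and numerical choices behind
`panpav`, and what the synthetic-data validation does and does not show.

## The map-to-pan model

The pipeline assumes the standard map-to-pan design: a pangenome built by
appending non-redundant novel sequence to a reference, per-accession short
reads mapped back to it, and gene presence scored from exon coverage. The
package starts from the *records* of that process (PAF hits, GFF3 gene
models, bedGraph depth tracks, metadata TSV) and never invokes aligners,
assemblers or gene predictors. Coordinates are 0-based half-open
internally; GFF3 (1-based closed) is converted on read and write.

## Non-reference extraction

Hits shorter than 300 bp or below 90% identity are discarded; both bounds
are inclusive because the defining phrases are "minimum of" and "at
least". The uncovered complement of the merged hit intervals is scanned
for runs of at least 500 bp; a contig with no hits at all is kept whole
when long enough. Contigs whose taxonomic hits are exclusively non-green
are removed; contigs with mixed hits are kept when green-plant hits cover
at least 90% of the union of all hit-covered bases. Contigs with no
taxonomic hits at all are kept: the screen removes identified
contaminants, not unclassified sequence. Adaptor/organellar screening is
expressed through the same operation by assigning those hits to the
non-green class.

Redundancy removal is a single deterministic greedy pass in cd-hit style:
segments sorted by length descending (ties by input order), each joining
the first representative it matches at ≥ 95% identity and ≥ 95% coverage,
else founding a new cluster. The multi-tool cascade this emulates
(iterated nucmer, then blast+/cd-hit) has no published iteration schedule,
so one well-defined pass is substituted; it is idempotent by construction
and the test suite asserts that.

**Pairwise identity.** Identity and coverage are computed from an optimal
pairwise alignment (match +1, mismatch −1, gap −2) in which the shorter
sequence is aligned globally and only the longer sequence's terminal
overhang is free — the convention under which cd-hit reports identity
"with respect to the shorter sequence". Two alternatives fail basic sanity
checks: fully penalised end gaps make the aligner smear a contained
sequence across its host (measured 71% identity for exact containment),
and fully free end gaps let two unrelated sequences align as a trivially
short perfect overlap (identity 100%). Identity is matches / alignment
columns between the first and last aligned pair; coverage is the aligned
span on the shorter sequence over its length. The dynamic-programming
aligner is quadratic and intended for synthetic-scale sequences (≲ 50 kb);
for real chromosome-scale data callers should supply precomputed
identity/coverage records instead.

## PAV calling

A gene is absent when strictly less than 20% of its exonic **bases** are
covered by at least *n* reads. "20% of its exon regions" could also be
read as 20% of the exon count; the base-level reading is adopted because a
depth track is defined per base and exon-count semantics would make calls
depend on arbitrary exon segmentation. The depth bins for *n* overlap at
80 in their printed form ("41 to 80, or 80+"); they are resolved as
(40, 80] → 8 and (80, ∞) → 10. The coverage comparison (depth ≥ n) and
the category thresholds below are the remaining boundary conventions:
absence is strict (< 0.20), so a gene at exactly 20% covered is present.
Mean depth is taken from metadata when supplied; otherwise it is estimated
as total track depth over total pangenome length.

## Pangenome statistics

Core requires presence frequency strictly above 0.97 and cloud strictly
below 0.03 (both parameters). Rarefaction samples accession orderings
without replacement (100 permutations by default, seeded) and reports
pan (union) and core (intersection) sizes per added accession; within
every permutation pan is non-decreasing and core non-increasing by
construction, and the tests assert it per permutation. The plateau report
uses the smallest K where the mean pan curve gains less than 0.5% over the
previous 10 accessions. The shared-gene matrix counts jointly present
genes (X^T X on the binary matrix). A gene is present in a clade when at
least one member carries it; Venn cells partition the union of present
genes exactly.

## Selection statistics

The two-sided Fisher p-value follows the minimum-likelihood convention —
the sum of hypergeometric point probabilities not exceeding the observed
table's, with a 1 + 1e-7 relative guard against floating-point ties, the
convention of mainstream implementations. The pmf is computed directly
from log-gamma terms, which keeps the exhaustive validation sweep (~164k
tables, all margins ≤ 30) fast; scipy's implementation serves as an
independent oracle in the tests, never as the implementation. FDR is
Benjamini–Hochberg (the source analysis says only "FDR"). Fold change is
the ratio of the larger to the smaller presence frequency; when the
smaller is 0 and the larger positive the fold is +∞ and passes the > 2
criterion, since the criterion is stated only as a lower bound. Favorable
requires FDR < 0.001, fold > 2 and domesticated frequency above wild;
swapping the groups maps favorable to unfavorable with identical p-values.
Ties in the landrace/cultivar partition go to a separate bucket rather
than either side.

Term enrichment is a flat per-term Fisher test against the background with
BH correction across terms. Graph-aware GO algorithms (elimination /
weighting, DAG propagation) are deliberately not reproduced; the term map
is flat and results are term identifiers only.

## Clustering

The accession tree is neighbor joining on binary PAV distances — a
deliberate substitute for maximum-likelihood inference on binary
characters, proportionate because the property consumed downstream is
clade grouping, not branch-length estimates. Hamming (simple matching) is
the default metric: shared absence is informative for clade structure in
gain/loss data; Jaccard is available where shared absence should be
ignored. NJ uses the standard Q-criterion with ties broken by the smallest
index pair in the current working order; a negative branch length is
clamped to zero with the deficit moved to its sibling so the pair's summed
length is preserved. NJ is exact on additive matrices, verified on 200
random trees. Bootstrap supports come from resampling gene columns with
replacement and counting, per internal split of the point tree, the
percentage of replicate trees containing that split; splits are encoded
canonically (the side not containing the lexicographically smallest leaf),
making supports invariant to input order. PCA centres gene columns and
uses SVD; component signs are fixed by making each component's
largest-magnitude loading positive.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: a panel of
wild, landrace and cultivar accessions in monophyletic clades (the
domesticated groups confined to the last clade), ploidy 2×–4× with
cultivars tetraploid by default, mean sequencing depth 30×, and a gene
universe of 2,500 core + 2,000 shell + 500 cloud genes over 3 clades × 20
accessions. Those defaults are the standard conditions used throughout the
validation; scaled-down fixtures in the unit tests shrink the gene counts
and the ploidy bonus together so the signal-to-noise structure is
preserved.

Shell genes start present at the root and evolve by per-branch Bernoulli
events (loss 0.10, gain 0.03 per branch) — not a continuous-time Markov
chain; per-branch events are sufficient to create clade-structured PAV
because events on internal branches are shared by all descendants. Cloud
genes are placed in at most max(1, 3% of accessions). Polyploids gain
Poisson(bonus × (ploidy − 2)) extra present genes drawn from their absent
set, with bonus 100 by default — additive inflation without modelling
homeolog resolution. Planted selection genes are drawn i.i.d. per
accession at their stated group frequencies. Truth categories are defined
by applying the core/shell/cloud thresholds to the realized truth matrix
(for constructed core genes the two views coincide; a design-cloud gene
promoted by ploidy flips is truthfully shell).

Coverage is simulated per base, not per read. A present gene's exonic
bases get i.i.d. Poisson(mean depth) counts; with probability `noise_fn` a
dropout leaves only a sub-20% fraction covered. An absent gene has zero
exonic depth when `noise_fp` is 0 (the noise-free closure case); otherwise
it carries light spurious coverage on < 8% of bases, upgraded with
probability `noise_fp` to a 35–60% covered spurious signal that defeats
the 20% rule. The noise parameters are therefore per-cell miscall
probabilities by construction — free parameters of the generator, not
estimates of any real dataset's mapping-noise structure. Default
`noise_fp = noise_fn = 0.005`.

What passing tests show — and what they do not: the validation
demonstrates that the implemented rules recover planted truth under the
generator's assumptions (independent per-base depth, exact planted
homology, flat contamination structure, i.i.d. selection genes). Real
data adds mappability structure, paralog cross-mapping, heterozygous and
dosage-dependent coverage in polyploids, and reference bias, none of which
the generator models; results on real panels depend on those factors in
ways these tests cannot certify.

## Problem sizes and determinism

The standard validation panel is 3 clades × 20 accessions × 5,000 genes
with 100 bootstrap and 100 rarefaction replicates, and the selection check
uses 20 replicates of 200 planted + 5,000 null genes at 30 + 30
accessions — sizes chosen so the entire validation (test suite plus
acceptance script) completes in a few minutes on one CPU while keeping
every binomial check well-powered. All randomness flows through
numpy `SeedSequence` streams keyed by (master seed, stream tag, unit
index), so outputs are byte-identical across runs and independent of
iteration order; per-accession coverage tracks can be generated lazily one
accession at a time without changing the draws.

## Known limitations

- The identity oracle is quadratic; it is not meant for chromosome-scale
  sequences.
- The greedy redundancy pass is order-deterministic but, like cd-hit, not
  globally optimal clustering.
- Fisher tests treat accessions as independent; relatedness within clades
  is ignored, as in the source analysis.
- The NJ tree is a distance-based summary; no substitution-model inference
  is performed, and branch lengths should not be interpreted as rates.
- Gene models with overlapping exons are rejected rather than merged.
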
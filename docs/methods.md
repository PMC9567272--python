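# Methods

This note documents the statistical procedures mycoflow implements, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Flooring and normalization

Low-biomass amplicon sequencing of multiplexed libraries suffers from index
hopping: reads are misassigned between samples, producing spurious
low-count features. Empirically this yields a bimodal per-feature,
per-sample read histogram with modes on either side of ~1000 reads, so the
pipeline zeroes every count below a **floor threshold** (default 1000,
integer, applied to raw counts only — normalized values are never
re-floored, and flooring a floored table is an error to prevent silent
double application). Flooring is idempotent as a map on counts.

Two normalizations follow:

- **Library normalization.** Each sequencing library *l* receives a factor
  `f_l = mean(reads/sample in l) / mean(reads/sample overall)`; each
  sample's counts are divided by its library's factor. Division (rather
  than multiplication) is the only direction that equalizes per-library
  mean depth at the grand mean, which is the factor's stated purpose.
  Means are computed on floored, pre-dilution counts: flooring precedes
  normalization in the processing order, and dilution correction is a
  separate, per-sample step. Empty samples count toward the means with
  zero reads. Both orderings relative to dilution are supported, but the
  default excludes dilution-corrected counts from the means.

- **Dilution normalization.** Samples diluted before sequencing (factors
  5–20, recorded in metadata; missing values default to 1) are multiplied
  back by their factor to restore original load.

**Taxonomic aggregation** sums features sharing a lineage down to the
target rank. Features with no name at the target rank group under their
lowest known rank, with the ranks below rendered `Other`
(e.g. `g__Cladosporium;s__Other`); aggregated feature ids carry the full
lineage path down to the target rank, which keeps ids unique when distinct
higher-rank contexts share a name. Aggregation conserves the grand total
exactly (integer sums are exact; normalized tables conserve to float
precision).

Presence, everywhere downstream, means count > 0 on a floored table.

## Two-stage control-anchored decontamination

The procedure assumes the cohort carries two classes of negative controls —
DNA-extraction blanks and tissue-free paraffin controls — which both
classes are pooled to define the control-overlap partition:

- species present only in controls → removed;
- species absent from every control → retained;
- species present in both → tested.

For each shared species and each **condition** (tissue type + tumor/NAT/
normal status), two one-sided tests ask whether the species looks enriched
in the condition relative to the control class of the current stage:
Fisher's exact test on presence/absence of the floored, normalized table,
and a rank-sum test on abundances of the *unfloored*, normalized table
(flooring would discard exactly the low-abundance gradient this test needs).
The rank-sum test enumerates all group assignments exactly when the
combined n ≤ 12 (midranks handle ties) and uses the tie-corrected normal
approximation otherwise; completely tied data returns p = 1.

Benjamini–Hochberg correction runs across species within each
(condition × test × control class) family — the per-condition phrasing of
the procedure implies families no wider than a condition, and splitting by
test keeps the two statistics' different null behaviors from mixing. A
species passes a stage for a condition if **either** test has p ≤ alpha
(0.05) and q ≤ fdr (0.2). The default retention rule demands that one and
the same condition pass both the extraction-control and paraffin-control
stages (`same_condition=True`); the looser any-condition-per-stage reading
is available as a flag. Retained shared species plus control-absent species
form the "fungal world". The procedure is level-agnostic and can be run on
ASV, species or any higher-rank table.

One-sidedness ("more prevalent / more abundant in the condition") is the
appropriate alternative for contamination screening, where only enrichment
over controls is evidence of tissue origin; the generic
`differential_prevalence` used for clinical two-group contrasts is
two-sided (no privileged direction) and applies a prevalence filter first —
a taxon must appear in ≥ 5% of samples and at least twice in one group.
Raising alpha or fdr can only grow the retained set (monotonicity of BH
step-up and of the pass rule).

Pairing between paraffin controls and their source blocks is not used
statistically; controls enter as pooled groups, as the group tests imply.

## NMI co-occurrence networks

Association between two taxa is measured on binary presence vectors over
the M samples of one tissue by the plug-in normalized mutual information
`NMI = (H(X)+H(Y)−H(X,Y)) / sqrt(H(X)H(Y))` with `0·log 0 := 0`.
Entropies use natural log internally; NMI is invariant to the base.
NMI ∈ [0, 1]; for binary vectors it is a function of M, the two presence
counts and the co-presence count only. The kernel orders the two margins
canonically before summation so that `nmi(x, y) == nmi(y, x)` bit-exactly.
When either vector is constant its entropy is zero and the ratio is
undefined; such pairs return NaN and are excluded from network families
rather than being scored 0 — the formula genuinely has no value there.

Significance comes from a weighted permutation null designed to preserve
sample-richness structure, a dominant driver of spurious co-occurrence in
presence data. Sample weights are
`w_i = (#observed taxa in sample i) / (#observed taxa in all samples)`,
with richness counted over the combined fungal + bacterial presence matrix
of the tissue's samples (weights are recomputed within each tissue's sample
set). Each realization independently reshuffles **both** vectors: a taxon
with k presences has them re-placed on exactly k samples, drawn by
sequential weighted sampling without replacement with probabilities
proportional to the weights (implemented with Gumbel-top-k keys, which is
equivalent and vectorizes; presence counts are conserved in every
realization). If k exceeds the number of positive-weight samples,
zero-weight samples are included with a logged warning. The p-value is the
fraction of 1000 realizations whose shuffled NMI is ≥ the observed value.

This tie-inclusive fraction estimator is discrete: its minimum attainable
value is 0, and because the null NMI has a large atom at its minimum, the
p-values are conservative (stochastically larger than uniform), with an
atom near p = 1. Calibration should therefore be judged one-sidedly —
P(p ≤ t) must not exceed t — together with the realized rejection rate at
nominal levels; an exact-uniformity test will always reject for this class
of estimator. An optional `(b+1)/(m+1)` smoothed estimator provides a
nonzero p floor for users who need one (default off).

Networks are built per tissue and per edge class (FF, BB, FB); BH runs
within each (tissue, edge class) p-value list and edges with q ≤ 0.2 are
retained — no additional raw-p threshold is applied. Each retained edge is
signed by the Pearson correlation of the two presence vectors. Randomness
is controlled by a single seed; each pair's shuffles come from a substream
derived deterministically from (seed, taxon names), so results are
independent of pair iteration order and stable under adding or removing
taxa.

With the raw-fraction estimator at 1000 shuffles, a null pair attains
p = 0 with probability slightly below 1/1001 (ties reduce it), and such
pairs survive BH at any FDR; expect roughly one false edge per thousand
null pairs in large networks. Raising `n_shuffles` lowers this floor
proportionally.

## Mycotypes and log-ratios

The mycotype module consumes any conditional co-occurrence matrix between
fungal genera and another modality (bacterial genera, immune cell
fractions) — e.g. the output of a neural co-occurrence model fitted per
data-submission center; fitting such models is out of scope here.

Processing: (1) rows are z-scored with their own mean and **population**
SD (zero-variance rows are zeroed and flagged); (2) entries inconsistent
across submission centers are dropped. The default consistency criterion
retains entries whose |median across centers| < SEM (sample SD with n−1,
divided by √n), the literal form of the published rule; because this
excludes entries on which all centers agree perfectly (SEM = 0), a
stricter alternative — every center within one SEM of the median — is
available behind a flag. The median matrix over retained entries feeds
(3) average-linkage, Euclidean-distance hierarchical clustering cut at the
highest partition into three clusters ("mycotypes" F1/F2/F3). Rows are
sorted lexicographically before linkage and labels renumbered by first
appearance, making the partition deterministic and row-order invariant.
(4) Features of the other modality are assigned to the mycotype whose
fungal members give them the largest **mean** co-occurrence (an alternative
max-over-members rule is a flag; "within-cluster maximum" does not
distinguish the two, and the mean is robust to single outlier members).
Exact ties break toward the lower-numbered mycotype and are logged.

Group comparisons use per-sample log-ratios of raw-count group sums with a
pseudocount of one added to **each group sum** (one per ratio term, not per
taxon — the groups are aggregated before the ratio is formed):
`LR = ln(Σ_num + 1) − ln(Σ_den + 1)`. Computing the difference of logs
makes antisymmetry `LR(A,B) = −LR(B,A)` bit-exact. The log base is
natural; between-group comparisons are base-invariant up to scale. The
pseudocount breaks exact scale invariance; the deviation under scaling a
sample's counts is bounded by `c·(1/Σ_num + 1/Σ_den)` and vanishes in the
large-count limit. The published three-mycotype fungal model (F1 =
*Malassezia*, *Ramularia*, *Trichosporon*; F2 = *Candida*, *Aspergillus*;
F3 = 18 further genera) ships as a package data file so log-ratio analyses
can run without re-deriving clusters.

## Synthetic cohort generator

`simulate_amplicon_cohort` emulates the structure the pipeline assumes, as a
pure function of spec + seed. Defaults (the benchmark cohort): two tissue
conditions × 100 samples, 50 extraction + 50 paraffin controls, six
libraries with depth multipliers 0.6–1.5, 20% of tissue samples diluted by
an integer factor in 5–20, 20 condition-enriched true fungal species
(prevalence 0.4 in their condition, 0.05 elsewhere, absent from controls),
5 contaminants present with probability 0.35 uniformly across all sample
classes — the uniformity that makes prevalence tests powerless for true
contaminants is exactly what the decontamination exploits — 30 bacterial
species, and 5 planted fungus–bacterium pairs drawn from a closed-form
2×2 joint with odds ratio 20.

Read counts for present organisms are log-normal (median 20 000 ≈ 20× the
floor, σ = 1); index-hopping noise is log-normal (median 100, σ = 0.7)
sprinkled at rate 0.05 over absent cells of all samples including
controls. After library multipliers, signal counts are kept at or above
the floor and noise counts below it, so the emitted histogram is bimodal
around the floor and flooring removes noise exactly — a deliberate
idealization: the generator reproduces the *bimodal histogram* the floor
exploits, not the mechanism of index hopping, and real data will have a
small mass of ambiguous counts near the floor that these tests do not
exercise. Diluted samples model strong amplifiers: their emitted counts
follow the same post-dilution distribution and their pre-dilution load is
defined as emitted × factor, so dilution normalization inverts the
dilution exactly. A minority of true species carry genus-only
classifications (exercising the `Other` aggregation path) and two species
are split across two ASVs.

Other simplifications to keep in mind: contaminant and signal abundances
share one distribution; bacterial tables carry no contaminants; there is
no taxonomic misclassification, chimera formation, or read-level error.
Passing recovery tests on this generator shows the *procedures* behave as
specified under their own assumptions, not that those assumptions hold in
any particular real cohort.

`simulate_codependent_pair` solves the 2×2 joint for given margins and
odds ratio in closed form (the quadratic root lying inside the Fréchet
bounds) and samples cells i.i.d. `simulate_mycotype_dataset` draws
negative-binomial genus counts (mean 200, shape 5) for two groups of
samples with a planted fold change on the F1 genera, for log-ratio
power/recovery checks.

## Problem sizes and determinism

The test suite runs the statistical checks at the following scales, chosen
so the full suite completes in a few minutes on one CPU: exhaustive NMI
oracle equivalence on all binary pairs of length ≤ 8; 10⁴ fuzzed pairs for
bounds; 200 null pairs × 1000 shuffles at M = 100 for calibration; the
40+40-taxa, M = 100 network recovery at 1000 shuffles; the default
(100/condition) cohort for decontamination and preprocessing invariants;
and 2 × 100 samples for log-ratio effect recovery. All stochastic steps
take explicit seeds; cohort generation, decontamination and network
construction are bit-reproducible given the seed, and network results are
additionally invariant to taxon iteration order via per-pair substreams.
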
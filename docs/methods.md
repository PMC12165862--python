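# Methods

This note documents the models implemented in `apobecsig`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that affect results.

## Mutation catalogs and APOBEC3 context

Single-base substitutions are classified into the standard 96 channels:
six pyrimidine-normalized substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) × 16 flanking contexts, in alphabetical order within each class
(`A[C>A]A` … `T[T>G]T`), matching the orientation and order of public
signature files. Substitutions at purine reference bases are
reverse-complemented before classification, so the catalog is invariant to
which strand a variant was reported on (property-tested by flipping a whole
genome).

A substitution is **APOBEC3-context** when its normalized channel is
`T[C>T]N`, `T[C>G]N` or `T[C>A]N` — the joint footprint of SBS2 and SBS13.
Exactly 12 of the 96 channels qualify. Note that in 96-channel space the
"TCN motif" set (5′ T with a mutated C) *is* this same 12-channel set,
because a central pyrimidine C admits only three substitution classes; the
clusters module exposes both names for clarity.

Mutations at contig boundaries (no flanking base) are skipped with a logged
warning and counted in a per-sample side tally, as are indels and
non-ACGT alleles. TMB is mutations per megabase of panel footprint; the
"high" flag fires at ≥10/Mb (the boundary value 10.0 is high). Whether
indels count toward the TMB numerator is the caller's choice; the CLI uses
SNVs + indels. Cohort QC drops samples with tumor purity strictly below
0.20; purity exactly 0.20 is retained and samples with no purity estimate
are retained unless `drop_missing_purity` is set — the handling of missing
purity is this package's documented default, not an asserted upstream
behavior.

## Signature refitting and dominant-process calls

Refitting solves the non-negative least-squares problem
`min_{e≥0} ‖m − S e‖₂` per sample (active-set solver from SciPy). This is
deterministic and scale-equivariant, so percentages `p_s = 100·e_s/Σe` are
invariant to catalog scaling. Percentages are grouped into processes
(Clock = SBS1+SBS5, APOBEC3 = SBS2+SBS13, HRD = SBS3+SBS8; anything else
stays its own group) and the group with the highest percentage is the
dominant process. Samples with fewer than `min_snv = 5` context-resolvable
SNVs are `not_evaluable`; exact ties break lexicographically on the group
name with a flag. The default refit inventory is SBS1, 2, 3, 5, 8, 13, 17,
18 — the signatures recurrently active in breast cancer — and is
configurable.

For extremely sparse samples a second scorer ranks candidate 96-simplex
mixtures by multinomial log-likelihood `Σ_c m_c log q_c` with each `q`
floored at `ε = 1e-6` and renormalized (the floor prevents −∞ for
candidates with empty channels), alongside cosine similarity. No trained
classifier layer sits on top of these scores; the likelihood/cosine ranking
is the whole scorer.

`SignatureRefitter` (fit/transform) and `DominantSignatureCaller`
(fit/predict) wrap this machinery in the scikit-learn estimator contract so
they compose with sklearn pipelines and model selection; the module-level
functions are thin wrappers around the same code.

## Panel-downsampling validation

To ask whether a targeted panel supports dominant-signature calling, rich
mutation sets are intersected with the panel footprint (1-based position
`p` is in 0-based half-open interval `(s, e]` iff `s < p ≤ e`), catalogs
are rebuilt, dominant processes re-called, and agreement with truth scored
(sensitivity, specificity, accuracy, PPV, NPV for APOBEC3-dominant
detection; Pearson r between full and panel APOBEC3 percentages). Only
samples with ≥5 panel SNVs enter the metrics; the excluded fraction is
reported. On synthetic cohorts "truth" defaults to the grouped argmax of
the generating mixture (unambiguous); a full-data-refit truth mode is
provided for parity with real-data workflows. On the default synthetic
cohort (500 samples, ~2,000 SNVs each, 1 Mb genome) accuracy rises
monotonically with panel fraction (≈0.85 at 0.5%, ≈0.93 at 2%, ≈0.98 at
10%, 1.0 at full footprint) and the 0.5–2% panels give exposure
correlations r ≈ 0.76–0.91.

## Margin-preserving permutation enrichment

The gene-level test asks whether samples mutated in a gene have higher
APOBEC3 exposure than wild-type samples, per gene, by two-sided Wilcoxon
rank-sum. Because hypermutated samples are mutated everywhere and long or
hot genes are mutated in many samples, raw p-values are compared against a
null that holds both margins fixed: the **curveball** algorithm randomizes
the binary gene×sample matrix by repeatedly picking two random rows and
reshuffling the columns where exactly one of them carries a 1, preserving
every row and column sum exactly. Each permutation restarts from the
observed matrix and applies `5 × min(n_genes, n_samples)` pair-trades (a
Strona-style burn-in; configurable). Uniformity over the margin class is
verified against brute-force enumeration on small matrices.

The final per-gene p is `#(p_random ≤ p_observed) / N` with `N = 10,000` by
default (ties count as ≤; an add-one `(k+1)/(N+1)` variant is available
behind a flag). BH FDR is applied to the observed p-values by default
(applying it to permutation p-values is a flag). Genes mutated in fewer
than 1% of the cohort are dropped before testing, then samples with no
mutation in a retained gene; genes mutated in every remaining sample are
dropped with a warning because the rank-sum comparison is undefined.

Rank-sum p-values use the exact permutation null when the smaller group has
≤8 members and the exposures are tie-free, otherwise the tie- and
continuity-corrected normal approximation; both branches are cross-checked
against an independent implementation in the test suite. Inside the
permutation loop the exposure ranks never change and curveball preserves
each gene's mutant count, so the statistic reduces to a dot product of the
permuted row with the fixed rank vector and the p-value to a precomputed
statistic→p map — this is what makes 10⁴ permutations × hundreds of genes
tractable.

Odds ratios (gene mutation vs APOBEC3-dominant status) use the 2×2
cross-product, with the Haldane–Anscombe +0.5 correction applied to all
cells when any cell is zero, and a Wald p from the corrected table.
Site-level enrichment runs Fisher's exact test (or logistic) per site with
BH across sites.

### Power note

Under the default null generator the permutation test is well calibrated
(type-I rate ≈ 0.04–0.06 at p ≤ 0.05). Detection of an injected
association is information-limited: with an odds ratio of 3 at 10%
baseline frequency in 300 samples, *any* test of the implied 2×2 contrast
has a noncentrality of ≈3.4 SD, so at the BH-adjusted threshold
(q < 0.1 over a 50-gene matrix ⇒ p ≲ 0.002) power plateaus near 60% — the
pipeline reaches that bound (and >90% power requires roughly twice the
sample size or an unadjusted threshold). This is a property of the design,
not of the implementation.

## Paired early/late samples

Within a patient, samples are ordered by collection date and each later
sample is compared with the earliest (consecutive pairing is an option,
matching the primary/first-biopsy convention). A late mutation is *shared*
when its exact site is in the early call set or when tumor-informed
genotyping reports ≥2 supporting reads at that site in the early sample;
otherwise *acquired*. Without genotyping data the classification falls
back to call-set membership (logged). Pairs sharing zero mutations are
excluded as probable mix-ups. Statuses partition the late sample's
mutations; raising the read threshold can only move mutations from shared
to acquired (monotonicity is property-tested).

The APOBEC3-context composition of shared vs acquired SNVs is pooled
across valid pairs into one 2×2 table and tested two-sided by Fisher's
exact test (pooling is the default; early-only mutations are tracked but
excluded from this table). Dominant-process transitions are tabulated over
{APOBEC3, Clock, HRD, other, not_evaluable}, and early-sample APOBEC3
percentages are summarized (median, IQR by linear interpolation, fraction
dominant) for pairs whose late sample is APOBEC3-dominant.

## Clustered mutations

Kataegis/omikli detection here is deliberately simple: maximal runs of
same-chromosome mutations with every adjacent inter-mutation distance
≤1 kb. Runs of 2–3 are omikli, ≥6 kataegis, 4–5 "intermediate" (all
configurable; the 6-mutation kataegis minimum is the classic rainfall
convention). An optional sample-adaptive threshold takes a low quantile of
IMDs from uniform-placement simulations at the sample's burden. This is
not a reimplementation of simulation-calibrated clustering tools, and
cluster counts from it should not be compared against results of those
tools; within the package it is used to flag and characterize tracts (TCN
fraction, APOBEC3-context fraction).

## Copy-number metrics

WGD: length-weighted fraction of profiled autosomal bases with major
allele copy number >1; the call requires strictly >50% (exactly half is
not WGD). FGA: length-weighted fraction of bases whose total copy number
differs from the diploid baseline or that show LOH (minor 0 with total
>0) — a fixed-baseline definition chosen because the upstream caller's
exact convention is not restated anywhere authoritative; a log-ratio
threshold mode is available. Sex chromosomes are excluded by default. Both
metrics are invariant to splitting segments with identical copy states.

## Survival

Kaplan–Meier, the k-group log-rank test and Cox proportional hazards are
delegated to lifelines. The KM median is the earliest time the estimate
reaches ≤0.5 (missing if never). Cox uses Efron tie handling (lifelines'
default and the less biased choice; note that exact data duplication then
shifts coefficients by ~1% because Efron redistributes within tied sets —
the Breslow version would be exactly invariant). Stratified fits share
coefficients across strata with separate baseline hazards.
Non-convergence or separation is returned as a flagged result. A ±30-day
biopsy-to-treatment window filter is available for eligibility trimming.

## Synthetic cohorts: what they emulate, and what not

The generators produce every input the pipeline consumes, with the
statistical structure the analyses assume:

* **Reference/panel** — an i.i.d. genome (default 1 Mb, GC 0.41) with
  non-overlapping genes (60 × 10 kb) and a panel taken as a random subset
  of gene intervals covering a target fraction of gene bases.
* **Catalog cohorts** — three dominant-process groups (APOBEC3 40%, Clock
  40%, HRD 20%) with mean mixtures separated by ≈35 percentage points of
  the dominant group and Dirichlet concentration 60 (keeping individual
  samples' group margins several SD from ties, so generator truth is
  well-defined); negative-binomial burdens (mean 2,000, dispersion 5 —
  WGS-scale, so that panel downsampling leaves realistic 10–40 SNV panel
  counts). Mutation placement is rejection-free: per-context site lists
  are precomputed once and positions drawn uniformly without replacement
  within a sample.
* **Signature spectra** — two bundled matrices, both synthetic: orthogonal
  indicator-like toy spectra (for unit tests where identifiability must
  not confound algorithm correctness) and richer stand-ins for SBS1, 2, 3,
  5, 8, 13, 17, 18 with peaks at each process's known motifs over smooth
  distinct backgrounds. They reproduce the qualitative channel structure
  of the public references, not their exact values, so absolute exposure
  numbers from real data will differ.
* **Gene matrices** — `P(mutated) = logistic(α_g + β_g·x_i)` with
  α = logit(0.10) and β = 0 except injected genes; exposures can be
  continuous or binary.
* **Paired cohorts** — 30 patients, 40 early SNVs, shared fraction 0.6,
  30 acquired SNVs, APOBEC3-context fractions 0.32 (early/shared) and
  0.52 (acquired) — the contrast the paired analysis is designed to
  detect; genotyping support Poisson(30) at shared sites, 0 at acquired.
* **Survival** — exponential event times per group, uniform censoring on
  (0, 60) months.
* **Copy number** — ~20 segments per genome with doubled fraction 0.75
  (WGD) or 0.25 (no WGD), forcible to any exact fraction for boundary
  tests.

Not emulated: germline variation, subclonal structure and CCF, sequencing
error, replication-timing or strand biases, mutation hotspots beyond
context composition, gene-length heterogeneity in the gene matrices, and
informative censoring. Passing tests therefore demonstrate correctness and
calibration of the *statistical machinery* under its stated assumptions —
not performance on real tumors, where signature misspecification, flat
signature collinearity and panel design dominate error.

All generators are driven by `numpy.random.Generator`; a single seed fans
out to per-stage child seeds via `SeedSequence`, and identical seeds give
byte-identical outputs (manifest hashes are reproduced across reruns).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use cohorts of 25–500 samples,
1 Mb genomes, 10³ permutations × 10–20 replicates for calibration, 100
replicates for power/recovery checks, and 500–1,000 null simulations for
survival calibration — sizes chosen so the whole suite completes in a few
minutes on one core while keeping Monte-Carlo error comfortably inside the
asserted bounds.
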
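# Methods

`ce3screen` implements the computational core of an RNA-centric
proximity-labeling screen: finding the proteins that bind a cryptic-exon
(CE3) region of the androgen-receptor pre-mRNA — the exon whose inclusion
produces the treatment-resistance splice variant AR-V7 — and triaging them
into clinically plausible splicing-factor candidates.  Every stage can be
exercised on synthetic data with planted ground truth; this note records
the models, the defaults and why, and what the synthetic experiments do and
do not demonstrate.

## Proteomics preprocessing

The screen has three arms — an unlabeled control, a non-targeting guide
(gNT) and a CE3-targeting guide (gAR) — quantified as protein-level iBAQ
intensities over four paired replicates.  The chain is fixed, in this
order:

1. drop contaminants, reverse-database decoys and identifications with
   fewer than 2 unique peptides;
2. subtract the paired unlabeled-control intensity from each guide-arm
   value, clamping negatives to 0 (removes endogenously biotinylated
   background);
3. keep proteins strictly positive in at least `min_present` replicates of
   *either* guide arm (default 3-of-4; generalized as `ceil(3n/4)`);
4. replace remaining zeros with half the minimum positive value of the same
   sample column, then log2.

The imputation pool is the sample column (arm × replicate) over retained
proteins; a `replicate` pool (both guide arms of a replicate index) is
selectable.  Positivity is strict, since a subtracted zero is a
non-detection.  Because steps 2 and 4 act per column, processing replicate
batches separately and concatenating equals a joint pass (asserted in
tests).  Multiplying all raw intensities by `c > 0` shifts every log2 value
by exactly `log2(c)` and changes no filter decision.

## Moderated-t enrichment

Per protein, the paired differences `d_k = log2 gAR_k − log2 gNT_k` give
`log2FC = mean(d)`, sample variance `s²` with `d = n−1` df, posterior
variance `s̃² = (d0·s0² + d·s²)/(d0 + d)` and `t = log2FC / sqrt(s̃²/n)`
on `d0 + d` df.  The prior `(d0, s0²)` is the standard empirical-Bayes
moment-matching fit of the log sample variances to a scaled log-F
distribution (digamma/trigamma estimating equations, Newton-inverted
trigamma).  Two details matter numerically:

- when the dispersion of `log s²` does not exceed the trigamma sampling
  floor, `d0 = +∞` is returned with `s0² = exp(mean(e))` where
  `e = log s² − digamma(d/2) + log(d/2)`.  The bias correction is
  essential: the naive geometric mean of `s²` underestimates `s0²` by
  `exp(digamma(d/2) − log(d/2))` (≈ 0.69 at d = 3) and inflates the
  type-I rate from 0.05 to ≈ 0.10;
- exactly identical variances (zero dispersion) are treated as known:
  `d0 = +∞`, `s0²` = the common value.

The implementation agrees with Bioconductor limma's `eBayes` on a shared
paired-difference matrix to ~1e-8 relative tolerance (checked in a test
that shells out to `Rscript`; limma is only ever an oracle).

Interactor calls use the screen's cutoffs: unadjusted p < 0.05 **and**
linear fold enrichment > 1.5 (log2 0.585), positive direction only —
depletion is never an interactor call.  Calls split into high-confidence
(BH FDR < 0.25) and low-confidence tiers.  The summary also reports the
two-directional count at the same cutoffs, since "differential enrichment"
totals can be read either way.

## Rotation gene-set test

A self-contained ROAST-style test of whether a curated set (e.g. published
AR-V7 splicing regulators) is enriched toward strong CE3 interactors.  Each
protein's paired differences are mapped by an orthonormal basis to an
effect coordinate (`sqrt(n)·mean`) plus `d` residual coordinates; under the
null these coordinates are spherically symmetric, so a uniform random unit
vector applied identically to all set members generates an exact null of
the set statistic while preserving inter-protein correlation.  Per-protein
scores are moderated z-values (moderated t mapped through the t CDF).  Set
statistics: `mean`, `floormean`, `msq` (default; for directional
alternatives the positive part is squared), `mean50`.  Alternatives: `up`
(default — the scientific claim is directional), `down`, `either`
(Bonferroni-doubled smaller one-sided p), `mixed` (magnitude only).
`p = (b+1)/(B+1)` with B = 9999 by default, so p ≥ 1/(B+1).  BH across
multiple sets.  Barcode output ranks the universe by −log10 FDR (ties:
|log2FC| descending, then id) and reports members' 1-based positions.

## Candidate triage

Three stages, in the screen's order: (1) intersect candidates with a
splicing-annotation list (an input file, not an embedded ontology);
(2) Pearson correlation with the per-sample target-transcript abundance
(SRPM), passing iff r > 0 and two-sided p < 0.05 — thresholds exposed,
since only the sign convention is established usage; (3) mean Pearson
correlation with each of three activity signatures, "strong" = top
quartile of candidates for that signature (`strong_quantile = 0.75`,
configurable — a rank-based rule is scale-free), selected iff supported in
≥ 2 of 3 signatures and passing stage 2.  Ranking is by the
across-signature mean correlation, ties by target correlation then id.
Stratum labels (e.g. treatment-naive vs exposed) add per-stratum
correlation columns; the pass decision uses all samples.

## Motif scanning

Overlapping occurrences of a k-mer are counted per window; the expected
rate under uniform composition is `4^(−k)` — once per 256 windows for the
TRA2-binding AGAA tetramer.  Fold = observed rate / expected rate; folds
above 1.5 are flagged (the field's selection bar for binding regions).
Unions of features (CE3 ∪ 3′-UTR) are scored on concatenated subsequences
with junction windows excluded.  A composition-adjusted expectation
(product of observed mononucleotide frequencies) is available behind a
flag; the uniform baseline is the default because it is the published
arithmetic.  U is mapped to T on read; only the sense strand is scanned.

## Splicing metrics

PSI = inclusion TPM / (inclusion + exclusion TPM); a zero denominator is
propagated as missing, never 0 (0 is a valid biological PSI).  ΔPSI is the
difference of group mean PSIs, tested by label permutation (999 draws,
two-sided); the transcript-variability empirical machinery of dedicated
splicing tools is deliberately out of scope.  Note the permutation floor:
with 3-vs-3 samples only 2 of 20 distinct assignments are extremal, so the
smallest attainable p is ≈ 0.1 regardless of B.  |ΔPSI| flags at 0.6 and
0.2 are reported.  Pooled exon usage averages exons within sample first,
then samples within condition (mean ± SEM); exon-effect ranks are ordinal,
most negative first, ties by exon id.

## qPCR formulas

ddCt with a reference gene (default RPL13A) and calibrator condition;
fold = `2^(−ΔΔCt)`, ΔCt averaged within condition before differencing
(per-replicate ΔΔCt is selectable and changes only the error propagation;
SEM is delta-method propagated, `fold·ln2·sem(ΔΔCt)`).  Pulldown fold
enrichment = `2^(−ΔΔCt(target arm)) / 2^(−ΔΔCt(control arm))` with each
arm's ΔΔCt input-normalized; the identity `fold(A,B)·fold(B,A) = 1` is
exact.  Percent input = `100 · input_fraction · 2^(Ct_input − Ct_enriched)`
— the single dilution correction; `input_fraction` is a required parameter
because the formula is undefined without it.  No amplification-efficiency
correction.

## Synthetic data: what it emulates and what it does not

`SimulationConfig` defaults are the study conditions: 4 paired replicates,
5% planted binders at log2 effect 2, replicate noise sd 0.5 (log2),
protein baseline spread sd 1.5 around log2 iBAQ 23, 2% endogenous-biotin
proteins elevated in all arms (the unlabeled control sits 3 log2 units
below the guide arms otherwise), 5% missing-completely-at-random dropout,
a 208-sample cohort with target correlations induced by a shared latent
factor (population r exact by construction), three 25-gene activity
signatures, and a 2000-nt transcript whose CE3 (15% of length) and 3′-UTR
(final 15%) carry a planted AGAA density of 2.4× the uniform rate plus one
GAAGAA enhancer hexamer.  Planted tetramers use floor+Bernoulli counts so
the expected extra density is exact; the enhancer's embedded AGAA is
counted against the planted budget.

Not emulated: intensity-dependent (MNAR) dropout — the screen's real
missingness mechanism is unknown, so dropout is MCAR; peptide-level
quantification and protein inference; read-level RNA-seq; non-uniform
background base composition.  Passing tests therefore show the statistics
are correct and calibrated under the stated model, not that the biology of
any particular dataset is reproduced.

A consequence of MCAR dropout worth stating: with half-minimum imputation,
a single guide-arm dropout drives a binder's paired difference to roughly
the column noise floor (≈ −12 log2 units), so sensitivity is capped near
`(1 − q)^4` for dropout rate q — ≈ 81% at the 5% default.  The recovery
experiments therefore run at their stated signal conditions with the
nuisance knobs (dropout, endogenous biotin) at zero, exactly as the
null-calibration experiments do; the acceptance script reports the
with-dropout sensitivity alongside as a diagnostic (≈ 0.75).

The synthetic reference transcript used for the enhancer-fold
demonstration is a stand-in generated by this simulator (the `SYNTH_ARV7`
id marks it); it reproduces the planted 2.4-fold density, not the
coordinates of any real transcript record.

## Problem sizes and numerics

Monte Carlo sizes used by the test suite and acceptance script: null
calibration 20 seeds × 2000 proteins; rotation calibration 500 repetitions
at B = 999; recovery 20 seeds × 1000 proteins; triage recovery 100 seeds;
motif recovery 100 seeds.  These sizes put the Monte Carlo error well
inside each asserted band.  p-values are clipped below at the smallest
positive double; trigamma inversion iterates Newton steps to 1e-10
relative tolerance; all tie-breaks (ranking, barcode, triage) are
deterministic by id so identical inputs give identical outputs.

## Known limitations

- The rotation test's `msq`/`mean50` directional variants follow this
  package's definitions (documented above); other implementations weight
  directions differently, so p-values are comparable only in calibration,
  not numerically.
- ΔPSI significance is permutation-based and needs several samples per
  group to be informative (see the floor above).
- The EB prior assumes exchangeable gene-wise variances; no trend or
  robust variants are provided.
- Cohort SRPM/FPKM values are affine transforms of Gaussians clipped at 0;
  clipping is negligible at the default scales but distorts correlations
  if means are pushed toward 0.
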
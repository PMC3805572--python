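# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Feature tables and quality control

A feature table holds nonnegative ion intensities for *m/z* features
(rows, keyed by mass-to-charge ratio and retention time in seconds) across
analytical runs (columns, sample × technical replicate). Missing values
are represented explicitly (`NA`) and are never conflated with a measured
intensity of 0; "detected" means non-missing **and** strictly positive,
since a zero in an extracted table conventionally denotes the absence of a
peak.

QC proceeds in the conventional order: a detection filter (default: a
feature must be detected in 100% of runs), then a technical-precision
filter on the replicate coefficient of variation. Within each sample,
CV = 100·sd/mean over that sample's non-missing replicates (samples with
fewer than two usable replicates are skipped); per feature the
within-sample CVs are aggregated across samples by the **median** (the
xMSanalyzer convention; the mean is selectable). The SD uses the n−1
(sample) denominator by default — replicate injections are a sample from
the injection-noise distribution — with the population (n) convention
selectable; the choice is recorded in the QC report because with
triplicates the two differ by a factor of √(3/2). Features with
CV ≤ 10% are retained. Both filters are idempotent and commute, and
replicate averaging (missing-aware arithmetic mean per sample) follows.

## Progression phenotype

The annual rate of motor progression is
(last follow-up − baseline UPDRS motor score) / elapsed years, with years
computed as days/365.25. When only an on-medication exam exists, the off
score is estimated as on-score + (population mean off − population mean
on); negative estimates are clamped to 0 with a warning since UPDRS scores
are nonnegative. Missing items are carried forward from baseline when a
baseline value exists (zero counts as present) and otherwise imputed by
the population item mean. Classification: with n subjects, the rapid
group is the top ⌈n/4⌉ rates; the reported cut is the ⌈n/4⌉-th largest
rate so that *rapid ⇔ rate ≥ cut*, with ties at the cut going to rapid.
On 233 distinct rates this yields exactly 59 rapid progressors. Negative
rates are legal (scores can improve); a `floor_zero` flag clamps them at
0 before classification for cohorts where that convention is wanted.

## Univariate screen

Each feature is tested for a group mean difference with a two-sample
t-test on log10 intensities (Welch by default — no equal-variance
assumption; the pooled-variance variant and the raw intensity scale are
selectable and logged). Missing values are dropped pairwise; features
with fewer than two usable samples in either group are flagged
untestable, and features constant in both groups get p = 1 with a flag.
P values are two-sided (direction is reported separately). Multiplicity
is controlled by Benjamini–Hochberg step-up FDR at q = 0.2: with ordered
p(1) ≤ … ≤ p(m), the significant set is every feature at or below the
largest rank i with p(i) ≤ (i/m)·q; adjusted q values are the usual
monotone minima. The Manhattan representation is −log10 p per feature
with a horizontal line at −log10 of the largest significant p (absent
when nothing is significant).

## OPLS-DA

The class response is a one-hot group indicator matrix, column-centred.
After autoscaling (column mean 0, SD 1 with the n−1 convention; constant
columns are centred only and flagged), **orthogonal signal correction**
removes components of systematic variation uncorrelated with class: per
component, the score t is seeded with the dominant PC of the current
matrix, orthogonalised against the response (t ← t − Y(YᵀY)⁻¹Yᵀt), a
normalised weight w minimising ‖Xw − t‖ is fit by least squares, t = Xw
is recomputed, and the loop runs to convergence (relative Δt < 10⁻⁶, at
most 100 iterations — on unstructured matrices the underlying power-type
iteration converges slowly and the best iterate is used with a logged
warning; the removed score is orthogonalised a final time, so the
orthogonality invariant |cor(t, y)| ≤ 10⁻⁸ holds regardless). The
matrix is deflated by t pᵀ with p = Xᵀt/(tᵀt). One OSC component is the
default, matching common practice in the OSC literature.

**PLS-DA** is NIPALS PLS2 on the corrected matrix: iterate w ∝ Xᵀu,
t = Xw, q ∝ Yᵀt, u = Yq to convergence; p = Xᵀt/(tᵀt); deflate X only
(Y-deflation is available but off by default — for a discriminant
response the predictive subspace is unchanged and X-only deflation keeps
scores interpretable). Two predictive components are the default (score
plots are two-dimensional). Components are sign-oriented so the
largest-magnitude loading is positive, making plots reproducible. R²X
and R²Y per component are tᵀt·pᵀp (resp. tᵀt·qᵀq) over the initial sums
of squares. Predictive scores are mutually orthogonal by construction.

Programmatically the stage is a model/results pair:
`OplsDa(table, meta, groups, n_pred, n_osc).fit()` → `OplsResults` with
`scores_frame()`, `loadings_frame()`, `t1_separation()` (standardised
mean difference of t1 between the first two groups) and `summary()`.
With `n_osc=0` the fit is exactly plain PLS-DA. No cross-validated Q² or
label-permutation validation is provided.

## PCLS feature selection

Per feature, the combined correlation R is the multiple correlation of
the autoscaled feature column on the first two predictive scores
(equivalently √(r₁² + r₂²) for orthogonal scores). Two flags are
reported: **candidate** — R at or above an absolute gate (default 0.95,
the level a feature needs to share ≥ 90% of its variance with the
discriminant plane) — and **selected** — the top fraction of features by
R (or by |loading|), default 5%. By default ranking and count run over
the full feature set (`selection_within="all"`); restricting both to the
gated candidates is available, in which case selected ⊆ candidate. The
absolute gate is strict by design: a feature whose group shift is d
standard deviations cannot exceed the point-biserial ceiling
r = d/√(d²+4) (≈ 0.6 at d = 1.5), so on realistically noisy single
features the gate flags only near-collinear redundancy; the rank-based
selection carries the recovery behaviour. The FDR∩PCLS intersection is
exact, with Venn counts logged.

## Correlation network and module preservation

Correlations are Pearson on log10 replicate-averaged intensities
(pairwise complete). Unsigned soft-threshold adjacency a = |r|^β with
β = 6 (the customary unsigned default; signed mode available), zero
diagonal. Topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
connectivity k = Σa; dissimilarity 1 − TOM feeds average-linkage
hierarchical clustering with a **static** tree cut (default height 0.99;
clusters below the minimum size, default 10, are relabelled 0 and module
ids are ordered by decreasing size). A static cut was chosen over the
dynamic tree cut for testability; the height and minimum size are flags.
The cut height interacts with sample size: the noise TOM floor scales
like the squared null correlation, so at n ≲ 40 samples the 0.99 cut
approaches the noise level and weakly separated modules can merge —
module *detection* is therefore best run on the pooled cohort, while
*preservation* only requires eigengenes of an already-defined partition.

The module eigengene is the first principal component of the
standardised member matrix, returned as a unit-norm per-sample vector,
sign-oriented so its average correlation with the members is
nonnegative (so it covaries with member intensities; a full sign flip of
the members flips the eigengene with them). The eigengene network is
A_IJ = (1 + cor(E_I, E_J))/2, and preservation of reference modules in a
test cohort is P = 1 − |A_ref − A_test| after recomputing eigengenes of
the *same* modules in both datasets. Per-module preservation is the
column mean of P excluding the identically-1 diagonal (includable via a
flag). At n ≈ 40 samples per cohort the sampling noise of eigengene
correlations puts intact-module preservation near 0.91 even when the
underlying structure is identical; a structure-destroying per-feature
permutation of the test samples drops the mean preservation by ~0.06,
which is the contrast to read, not the absolute value.

The target-correlate neighbourhood reports Pearson r of every feature
against a chosen target with a two-sided t-distribution p value
(r√((n−2)/(1−r²)) on n−2 df) and partitions |r| ≥ 0.3 hits by sign.
Published lists of this kind sometimes quote p values inconsistent with
the t-based computation at the stated n; this implementation reports the
t-based value.

## Single-point quantification

A response factor RF = reference concentration / mean reference
intensity (arithmetic mean over replicate injections; median selectable;
optional blank subtraction floored at 0) converts replicate-averaged
sample intensities to concentrations: conc = RF × intensity.
Quantification is linear and the calibrant round-trips exactly. Group
comparison is one-way ANOVA plus Tukey HSD via the studentized-range
distribution (Tukey–Kramer for unequal n); when all values are identical
the degenerate answer (F = 0, p = 1, all adjusted p = 1) is returned
explicitly.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes, at the
study's design scale: 100 samples (20 controls, 41 slow, 39 rapid)
analysed in triplicate, *m/z* uniform on 85–850, and by default 1,000
features (a desk-scale stand-in for the several-thousand-feature tables
real extractions produce).

Per feature j and sample i the true log10 intensity is
μ_j + σ_s·z_ij with μ_j ~ N(5, 0.5²) across features and σ_s = 0.5
(log-normal ion intensities are standard for LC-MS). Background features
have independent z; members of module k share a latent factor:
z = √r·f_k + √(1−r)·ε with r = 0.7, so pairwise within-module
correlation is exactly r in expectation. Module factors themselves share
a systemic driver (f_k = √ρ·g + √(1−ρ)·h_k, ρ = 0.3): real metabolic
modules are inter-correlated, and without this the eigengene network is
flat (all adjacencies ≈ 0.5) and preservation against a permutation null
is vacuous. ρ = 0.3 keeps between-module feature correlation (0.21) far
below the within-module 0.7 so module detection is unaffected. Effect
features (default 10, disjoint from modules) are shifted by
d·σ_s (d = 1.5) in the rapid group.

Technical replicates multiply the true intensity by exp(N(0, s_j²)) with
s_j chosen from the feature's target %CV via CV² = exp(s²) − 1.
Per-feature true CVs are log-normal across features (median 10%,
geometric SD 2): real features are heterogeneous in technical precision
— a single shared CV of 10% would let essentially every feature pass the
CV ≤ 10 filter, because a 3-replicate SD estimate is biased low (median
chi factor ≈ 0.83) — and the heterogeneous model reproduces the
qualitative behaviour of real tables, where the CV filter removes a
large fraction of features. Missingness, when enabled, is applied
uniformly at random after noise (real missingness is intensity-dependent;
this generator does not model that, nor chromatographic drift, batch
effects, or adduct/isotope structure).

Identical configurations (including the seed, default 17) produce
bitwise-identical cohorts.

**What passing recovery tests does and does not show.** Planted effects
are clean mean shifts on otherwise well-behaved log-normal features, so
sensitivity/FDR results certify the machinery (test statistics, step-up
procedure, score computation, module algebra), not performance on real
serum data with drift, heavy tails, and correlated missingness. Absolute
feature counts from the real study (e.g. how many features pass a given
filter) are properties of the instrument and cohort and are not
reproduced by design.

## Numerical conventions and edge cases

- SDs use n−1 throughout (autoscaling, CV default, eigengene
  standardisation) unless the population convention is selected.
- Constant columns: flagged and centred only (autoscaling), excluded with
  a warning (adjacency), an error (constant network target, degenerate
  module).
- Non-convergence of OSC/NIPALS returns the best iterate with a logged
  warning; invariants (score orthogonality, response orthogonality) are
  enforced by construction, not by convergence.
- BH on vectors containing NaN: untestable features get q = NaN and are
  never significant.
- Multivariate stages require a complete matrix; residual missing values
  after replicate averaging are column-mean imputed on the log scale.
- All randomised stages take an integer seed (default 17) and log it.

## Problem sizes used in the shipped checks

Simulation-based checks run at m = 500 features, n = 40 per group (the
study's two-arm size): 1,000 replicates for the global-null BH
calibration (the zero-discovery probability equals 1 − FDR ≈ 0.8, so the
estimate needs ~0.01 MC precision to be meaningful), 1,000 ANOVA null
sims, 50 seeds for planted-effect recovery, and 20 seeds for module
detection (n = 80 samples pooled) and preservation (40/40 split). The
end-to-end run uses the default 1,000 × 100 × 3 cohort.
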
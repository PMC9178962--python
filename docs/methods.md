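# Methods

This note documents the models, conventions and design choices behind
`msageing`, and what the synthetic-data experiments do and do not show.

## Morphometric similarity networks

For each subject, the seven regional features are z-scored across regions
(sample SD, ddof = 1), each pair of regions is Pearson-correlated over its
7-feature profile, and regional mean MS is the column mean of the resulting
matrix **excluding the diagonal** (including the self-correlation of 1
would add ~1/N to every value and break the weighted-degree reading;
regional MS = weighted degree / (N − 1)).  Two conventions are fixed and
recorded in outputs:

* z-scoring is within subject, across regions, per feature.  The
  alternative (across subjects) would make one subject's network depend on
  who else is in the file; the within-subject convention matches the method
  literature this analysis builds on.
* With only 7 feature samples per correlation, individual MS entries are
  coarse (sampling SD ≈ 0.4 at ρ = 0).  No smoothing is applied; the
  regional mean over N − 1 partners does the averaging.

A feature constant across regions is a hard error naming the feature;
missing regions are hard errors, not imputed — the parcellation is a fixed
ordered label list (360 by default), not an atlas file.

## Normative trajectories

Ordinary least squares on a centred-age design (for conditioning;
coefficients are reported on the raw-age scale), degrees 1–3.  Adjusted
R² = 1 − (1 − R²)(n − 1)/(n − p − 1) with p = degree; the exclusion rule is
exactly adj R² < 0.  Degree selection uses per-region nested F-tests
(`F = ((RSS_small − RSS_big)/Δp) / (RSS_big/df)`) aggregated cohort-wide:
the selected degree is the largest whose improvement is significant at
α = 0.05 in a majority of regions.  α and the majority threshold are
configurable and logged; on the default synthetic cohort this selects the
quadratic, which is also the generating model.

Shape classification uses the slope `a1 + 2·a2·age` at reference ages 27
and 60 (configuration defaults, not constants): (+,+) increasing, (−,−)
decreasing, (+,−) convex, (−,+) concave.  A slope of exactly zero at a
reference age counts as positive — a measure-zero tie-break, fixed so the
partition is total.

## Deviations and accelerated-ageing consistency

**Sign convention.** Deviation = observed − predicted.  Under this sign a
subject sitting *below* a declining trajectory — where an older person
would sit — has a negative deviation, which is what the direction rules
require ("negative deviations from decreasing trajectories are consistent
with accelerated ageing").  The convention is written into every output
and can be flipped.

Age categories are half-open `[lo, hi)` with the last closed, over the
default partition 20–30, 30–35, 35–40, 40–45, 45–60.  Ages outside the
partition are dropped with a logged count (configurable to a hard error);
ages outside the trajectory fitting range are evaluated by the quadratic
anyway and flagged `extrapolated`.

**Direction rule.**  The quadratic's slope is linear in age, so its sign on
a category is fixed by the endpoint signs: positive throughout → +1
(positive deviations accelerated-consistent), negative throughout → −1,
turning point strictly inside → indeterminate (0).  This single rule
reproduces the four enumerated class-based cases (increasing, decreasing,
convex/concave with the turning point above or below the category)
whenever the category lies inside the reference span [27, 60], and the
test suite verifies that equivalence on 1000 random pairs.  For categories
that extend below 27 the class labels can misdescribe the curve inside the
category (a turning point in [20, 27)); the slope-sign rule follows the
curve, not the label.  Indeterminate is returned rather than guessed when
the turning point splits a category.

Per region × category, one-sample t-tests against zero; FDR is applied
across regions within each category.  Benjamini–Hochberg is the default;
a Storey-style q-value (median-λ π₀ estimate) is available, and the choice
is recorded in every results file.  The optional permutation test flips
deviation signs per subject, sharing flips across regions so the spatial
correlation of the null is preserved (5000 flips by default, seeded).
Zero-variance deviations have undefined t and are reported non-significant
with a `degenerate` flag.

## Case-control statistics and the PAL model

Pooled-variance two-sample t-tests by default (Welch optional, choice
recorded); label permutations are run jointly across regions.  Cohen's d
uses the pooled SD with (nA + nB − 2) weights and no small-sample
correction.  Covariates are deliberately omitted by default (the groups
the analysis is designed for are matched on age and sex); an optional
residualization hook is off.

PAL total errors are modelled as `errors ~ age + group`, with main-effect
F-tests from single-term deletions of the additive model and the
interaction F from additive vs full.  A per-age-category Cohen's d table
accompanies the fit.

## Brain age

LassoCV over a 50-point logarithmic penalty grid (`eps = 0.01`, 5-fold
shuffled CV, seeded; one-standard-error rule off).  The path is stopped at
2000 coordinate-descent iterations — on correlated regional MS the deepest
(near-OLS) penalties converge slowly, and their CV error is already far
past the minimum.  Gap = predicted − calendar age, so an older-looking
brain has a positive gap; the convention is recorded and reversible.  Raw
gaps anticorrelate with age on held-out data (regression to the mean); the
training report quantifies this correlation from out-of-fold predictions
at the selected penalty, and a linear age-bias correction is available but
off by default.

## PLS brain–cognition model

Predictor (subjects × regions MS) and outcome (age, PAL total errors)
columns are z-scored before fitting — age in years and error counts do not
share a scale.  The model is sequential-deflation PLS2 (NIPALS, via
scikit-learn, with the inner power-iteration tolerance tightened to 1e-22
so component-1 weights match the cross-covariance SVD direction to 1e-10).
Outcome variance explained per component is computed from the mutually
orthogonal X-scores: `pct_k = Σ_j q_kj² ·‖t_k‖² / Σ‖Y‖²`.  Scores and
loadings are sign-aligned so every component correlates non-negatively
with the first outcome column.  Permutation significance shuffles outcome
rows jointly (preserving the age–PAL coupling) and uses the add-one
estimator `p = (1 + #{null ≥ obs})/(1 + n_perm)`, so the smallest
attainable p is 1/(n_perm + 1).  Subjects with missing behavioural data
are dropped listwise.

## Synthetic cohorts

The generator is the package's test bed: it must produce data whose ground
truth every downstream stage can be checked against.

**MS level.**  Regional MS is written directly as the quadratic trajectory
value at the subject's (possibly injection-shifted) age plus Gaussian noise
(`noise_sd`, default 0.015 MS units).

**Feature level.**  Each region's 7-feature profile is

    x_r = alpha_r · u + c_r · e_r

with `u` a fixed zero-mean template (six equal-magnitude entries, one
zero, so the per-feature standardization is near-isotropic on the template
span) and `e_r` per-subject noise projected exactly orthogonal to
span{1, u}.  Writing `t_r = alpha_r/√(alpha_r² + c_r²)` for the unit-scale
alignment, the MS entry for two regions is `t_r·t_q` up to O(1/√N) noise,
so regional mean MS is `t_r(S − t_r)/(N − 1)`, `S = Σt`.  Given target MS
values the generator solves this fixed point for `t` (damped iteration,
clipped at |t| ≤ 0.95).  Because the network stage centres each feature
across regions, the template coefficients must satisfy `Σ alpha_r = 0`;
row scales `rho_r = exp(−β t_r)` with `Σ t_r rho_r = 0` achieve this while
leaving row-normalized alignments — hence the similarity structure —
untouched.  Realized regional MS tracks the targets with slope ≈ 1.0–1.08
and per-subject SD below 0.01 across the lifespan.

Two consequences are documented rather than hidden.  First, a feasibility
envelope: the fixed point requires sign-balanced targets with
`max|m| ≲ √((N·mean(m) + 1)/(N − 1))`, so the default trajectories keep
|MS| ≤ ~0.1 — a deliberately scaled-down regime relative to empirical MS
matrices (where hubs reach ~0.3–0.4).  Shapes, statistics and the whole
analysis chain are unaffected by the scale.  Second, a detectability
floor: trajectory-shape tests condition on |slope| ≥ 1e-3 MS/year at both
reference ages; flatter regions are legitimately ambiguous at n = 665 with
the default noise.

**Default trajectory family** (one draw per region, seeded): class counts
121/119/57/63 (increasing/decreasing/convex/concave, rescaled for smaller
parcellations); slopes at the reference ages drawn uniformly per class —
decreasing regions at 1.8–2.8 × 10⁻³ MS/year so that a +10-year injection
(≈ 0.02 MS shift) is detectable in an age category holding ~25 of 183
patients with noise SD 0.015 (one-sample t ≈ 6, far beyond the BH
threshold at q = 0.01): the injection-detectability guarantees the test
suite asserts were designed into the defaults by this power analysis, not
observed post hoc.  An optional `n_noise` subset (48 by default in the
full-scale scenario) is replaced by flat pure-noise trajectories to
exercise the adjusted-R² exclusion rule; under the null, adj R² < 0 has
probability `P(Beta(1, (n−3)/2) < 2/(n−1))` ≈ 0.63 at n = 665, and the
observed exclusion rate is checked against that value.

**Injection.**  Patient subjects have their trajectories evaluated at
`age + delta_years` in a configurable affected set (default: all regions
with decreasing normative trajectories).  This encodes the *hypothesis* of
trajectory-consistent accelerated ageing as ground truth; it does not
claim the empirical spatial pattern of any disorder.

**PAL scores.**  `errors = b0 + b_age·age + b_group·[patient] + noise`,
truncated at zero and rounded (counts); first-trial memory score is a
decreasing function of errors on the task's 0–24 scale.  Defaults
(b0 = 12, b_age = 0.35 errors/year, b_group = 12, noise SD 10) give a
group effect of d ≈ 1.2 and a clear age main effect at n = 230; per-category
group effects can be supplied for calibration experiments.  Truncation
and rounding slightly inflate realized d for large effects — the
calibration test therefore compares replicate-averaged d within ±0.3.

**What the synthetic experiments do not show.**  Uniform age densities, no
scanner/site effects, no sex differences, no realistic cortical geometry,
independent Gaussian noise across regions (real morphometry has spatially
correlated errors), and MS magnitudes below empirical scale.  Passing
tests demonstrate that the *pipeline* recovers what it is pointed at under
its stated assumptions — not that those assumptions hold in any MRI
cohort.

## Determinism and provenance

All randomness flows from named seeds (`numpy` Generators; no global
state); pipeline stages draw from named children of the run seed, so a
config run twice yields bit-identical bundles (floats are serialized with
shortest round-trip repr, and no timestamps are written).  Every results
file embeds the config hash, parcellation hash, seed, FDR method and the
two sign conventions (deviation, gap).

## Problem sizes used by the test suite

Unit tests run on 12–40-region parcellations and cohorts of tens of
subjects; the end-to-end property tests use the full 360-region,
n = 665 + 331 scale for trajectory/deviation/brain-age recovery, 20
replicates for injection detection, 200 replicates at 60 regions for FDR
calibration, and 200 × 199 permutations at n = 30 for PLS p-value
uniformity.  These sizes were chosen to keep Monte-Carlo error well below
the asserted margins.
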
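# Methods

This note documents the statistical procedures implemented in
`vocscreen`, the design of the calibrated synthetic-data generator, the
numerical choices made where the design was genuinely open, and what the
passing test suite does and does not demonstrate about real data.

## The analysis pipeline

### Differential-VOC extraction

Candidate species are screened on the TIC channel with three rules,
applied conjunctively:

1. **Area floor** — mean TIC area above `min_tic_area` (default 10,000
   instrument units) in at least one group.  The screening rule's
   original wording does not say whether "raw area … was more than
   10,000" refers to a group mean or to any single sample; we default to
   the group mean (the only group-level quantity used elsewhere in the
   cascade) and expose `area_mode="any_sample"` as the alternative
   reading.
2. **Detection** — nonzero TIC in at least `min_detected_subjects`
   (default 3) subjects of at least one group
   (`detection_scope="pooled"` is the alternative reading).
   "Not detected" is encoded as all-zero areas, never as missing values,
   so this predicate is crisp; a configurable detection floor zeroes
   sub-floor areas on read.
3. **Fold window** — positive/control ratio of mean TIC areas strictly
   above 1.5 or strictly below 0.7.  The ratio is oriented cases over
   controls.  A zero control mean with nonzero case signal counts as an
   (infinite) increase.

Survivors are tested on the **quantifier ion** — the fragment m/z with
the largest summed area across all subjects, ties broken toward the
smaller m/z — with the Mann–Whitney U test.  A candidate is
*significant* when its one-tailed p ≤ 0.05; the significance call uses
the one-tailed column because the original six-biomarker panel includes
species starred only there.  Both p-values are always reported.
Significant species confirmed against commercial standards form the
*combination-eligible* subset used for combined indices; the historical
panel's 2-acetyl-2H-tetrazole is the example of a significant but
unconfirmed species that is excluded from combinations yet retained as a
discriminant feature.

### Exact Mann–Whitney U

U is computed from midranks (U₁ + U₂ = n₁n₂, ties counted half).  For
n₁ + n₂ ≤ 20 and tie-free data the p-value is exact: the null
distribution of U is enumerated by the standard dynamic-programming
recursion c(i,j,u) = c(i−1,j,u−j) + c(i,j−1,u), with total mass
C(n₁+n₂, n₁).  The reporting convention is one-tailed p = the smaller
tail, two-tailed p = min(1, 2 × one-tailed) — the halving pattern the
field's tables print.  With ties or larger samples the normal
approximation with tie-corrected variance (no continuity correction) is
used.  A constant pooled sample is flagged degenerate with p = 1.

At n₁ = n₂ = 9 the smallest achievable two-tailed p (complete
separation, U = 0) is 2/48,620 ≈ 4.11 × 10⁻⁵ — the value behind a
"p < 0.0001" entry for a fully separating marker.

### Quadratic discriminant

Two-class Gaussian QDA with class-specific covariances (sample
covariances, denominator n − 1) and equal priors by default (the design
is 9 vs 9; priors are configurable).  The score is expanded into
explicit polynomial coefficients (constant a₀, linear a, symmetric
quadratic matrix C; see README) so that the rule can be printed and
audited cell-by-cell the way spreadsheet discriminant reports are.  The
expansion is verified against the direct log-density difference at
1 × 10⁻⁸ relative tolerance.

Conventions: positive scores indicate the case class; the boundary
score = 0 is judged positive; any missing feature yields "unknown",
never imputation.  Fitting requires more subjects than features per
class and covariance condition numbers below 10¹²; optional shrinkage
blends each covariance toward its diagonal.  Box's M (with the standard
chi-square approximation, df = p(p+1)(g−1)/2) accompanies every
training report, since heterogeneous class covariances are what justify
QDA over LDA.

Training-set discriminant probability (percent correct per class) is
reported as-is, with no cross-validation — mirroring the original
report's training-only evaluation; this is optimistic and documented as
such below.

### Combined indices and ROC

A combined index is the vector of fitted values (unstandardized
predicted values, PRE-1) from OLS of the binary diagnosis indicator
(control = 0, case = 1) on the member VOCs' quantifier areas.  The
original description never names the dependent variable; the binary
indicator is the standard recipe for this "linear-regression combination
before ROC" workflow and is recorded here as a documented assumption.

ROC analysis is rank-based: AUC = (concordant + ½ tied)/(n₁n₂), which
coincides with the trapezoidal curve integral absent ties (the printed
AUCs are all multiples of 1/81, consistent with tie-free 9 × 9 data).
If the raw AUC is below 0.5, auto-orientation negates the marker
(decreasing markers such as hexanoic acid then report the
above-0.5 AUC).  The screening cutoff maximizes the Youden index
(sensitivity + specificity − 1), ties broken toward higher sensitivity.

### Index–score correlations

Pearson (and Spearman) correlation of an index against cohort scores,
restricted to subjects with a non-missing score — the clinician-rated
GRID-HAMD exists only for cases, so those correlations use n ≤ 9.  A
switch can exclude a designated subject (the agoraphobia-without-MDD
case of the original cohort) from GRID-HAMD correlations; default off.
Strength labels follow the Evans convention on |r| with bins closed on
the left: [0, .20) very weak, [.20, .40) weak, [.40, .60) moderate,
[.60, .80) strong, [.80, 1] very strong.

Curve estimation fits quadratic and cubic polynomials by least squares
with the overall F-test, F = (R²/k)/((1−R²)/(n−k−1)) on df (k, n−k−1).
The historical figure legends print denominator df n − 1 (e.g. "F(2,
17)" at n = 18); we implement the standard df and note the discrepancy
rather than reverse-engineer it.  A saturated fit (n = k + 1) reports
R² = 1 with a degenerate F.

## The synthetic-data generator

The raw per-subject tables of the pilot cohort are not deposited, so the
generator emulates their published statistical structure.  Its defaults
*are* the study conditions; they are not tuning knobs.

**Named effects.**  Each of the 20 published differential-VOC rows
becomes an `EffectSpec` with the printed group means and SEMs of the
quantifier-ion area (SEMs refer to the calibration cohort of n = 9, so
per-subject SD = SEM·√9).  Default model: a lognormal matched to the
group mean and SD — areas are positive and right-skewed, and several
printed SEMs exceed half the mean, which a normal model cannot produce
without negative areas.

**Outlier rows.**  For three rows the printed numbers are mutually
inconsistent with *any* moment-matched two-parameter model: a huge mean
ratio (up to 45-fold) and SEM ≈ mean, yet a non-significant rank test.
That signature means one extreme subject dominated the group.  These
rows (allyl isothiocyanate — control side; 1-butene 4-isothiocyanate and
2,5-dichlorophenol — case side) use a bulk + outlier mixture: n − 1
subjects follow the other group's distribution (optionally scaled by a
bulk fold) and one subject carries the excess mean, which reproduces
both the printed moments and the printed rank overlap.  The assignment
was made from analytic implied-AUC calculations on the printed values.

**TIC channel.**  The screening cascade operates on TIC areas, but the
published table reports quantifier-ion areas, and the two need not move
together (the TIC aggregates every fragment).  Indeed nine of the 20
rows have quantifier folds inside the (0.7, 1.5) window although all 20
were nominated.  The generator therefore plants a TIC fold per effect
species: the quantifier mean ratio when that ratio is already ≤ 0.5 or
≥ 2.0, else a clear contrast (3.0 up, 1/3 down) in the same direction.
TIC dispersion is modelled separately as lognormal with CV 0.15 around
the group's planted TIC mean (base level = `tic_scale` × control
quantifier mean; `tic_scale` defaults to 3.0 and is flagged as
unvalidated, the TIC/quantifier ratio being unreported).

**Small-cohort conditioning.**  At the study's size (9 vs 9) sampling
noise would scramble which rows come out significant.  Because the
printed p-value columns are part of the calibration, small-cohort mode
(group sizes ≤ 20) redraws each species — up to 500 attempts — until its
exact one-tailed p falls on the published side of α = 0.05, and redraws
the texanol block until min(case) > max(control) (the published
complete separation).  This is the same redraw-until device in both
cases.  At larger sizes both devices are off, so parameter-recovery
checks measure the unconditioned marginals; forcing separation at
n = 5000 would also distort the texanol means by tens of percent, since
the two lognormals genuinely overlap.

**Stratified sampling at large n.**  Large synthetic cohorts draw each
lognormal by stratified inverse-CDF sampling (one uniform per
equal-probability stratum, then shuffled).  The marginal distribution is
unchanged while empirical group means converge to the configured means
fast enough that a 5,000-per-group draw recovers every configured mean
within well under 1% even for the heaviest-tailed species.

**Texanol–isomer dependence.**  In the case group, texanol and its
isomer are drawn through a Gaussian copula with correlation 0.8094 (the
published case-group Pearson r); control draws are independent.  At
n = 10,000 the sample Pearson r recovers the planted value within
±0.02 (the lognormal margins are nearly normal at CV ≈ 0.08, so copula
attenuation is negligible).

**Background species.**  The remaining 137 species carry no group
effect: per-species mean areas log-uniform in [10³, 10⁶], per-subject
CV 0.2, identical in both groups.  Three randomly chosen background
species are zeroed in all but two subjects to exercise the detection
rule (per-VOC detection counts are unpublished; this default simply
guarantees the filter path is covered).  Species metadata (retention
times, fragment m/z sets) are deterministic functions of the species
index, so changing the seed changes areas but never the species list,
subject ids or group sizes.

**Cohort scores.**  Questionnaire scores are rounded truncated normals
matched to the published group means/SEMs and clamped to their
documented ranges (Kihon CL 0–20, TMIG-IC 0–13, JST-IC 0–16, DSKC and
DSKC-self 0–5, SDS 20–80).  The clinician-rated GRID-HAMD is generated
only for cases (mean 12.22, SEM 1.526, floor 7 — the inclusion cutoff)
and is missing ("n.d.") for controls.  Ages and sexes replicate the
matched design (six men, three women per group, at the published ages).

**Reproducibility.**  A seed is mandatory.  All randomness flows through
named substreams of the single seed (one per species, plus dropout,
TIC and cohort streams), so adding a stage never perturbs another
stage's draws, and a rerun of the same configuration is byte-identical.
The packaged default fixture uses seed 2015.

## What the tests show — and what they do not

The suite demonstrates that the *machinery* is correct: exact rank-test
enumeration against brute force, QDA expansion against log-density
oracles, AUC against the U-statistic identity, Box's M against an
independent implementation and a calibrated type-I error rate, and an
end-to-end fixture that reproduces the published analysis structure
(20 nominated, 6 significant, perfect training discrimination,
heterogeneous covariances).

It does not validate the biomarkers themselves.  The generator emulates
summary statistics, not real urine chemistry: no chromatographic drift,
co-elution, batch effects, fragment-ratio chemistry or recruitment
funnel are modelled, and the small-cohort conditioning reproduces the
published test outcomes *by construction*.  Passing tests therefore say
nothing about how the panel would perform on new cohorts.

## Known limitations

* No multiple-testing correction anywhere in the cascade — faithful to
  the original analysis, and anti-conservative by construction;
  157 species at α = 0.05 invites false nominations on null data (the
  suite checks the rate stays within the expected band, not that it is
  zero).
* Training-set discriminant probability is optimistic; with 6 features
  and 9 subjects per class, perfect training separation is weak evidence
  by itself.  No cross-validation is implemented, mirroring the original
  report.
* The TIC/quantifier area ratio (`tic_scale`) and the planted TIC folds
  are unvalidated modelling choices; only their qualitative role
  (making the published nominations recoverable) is exercised.
* AUC confidence intervals and logistic-regression combination are out
  of scope.
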
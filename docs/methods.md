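# Methods

This note documents the statistical model behind `drdtrial`, the choices
made where the published analysis left the mechanics open, and what the
synthetic generator does and does not emulate.

## Units, standards, and case definitions

The analysis unit is an eye or a participant (a cluster of one or two eyes).
Each eye carries a **Level I prognostic standard** (ETDRS severity level and
DME flags graded from widefield stereo photography plus OCT) and optionally a
**Level II reference standard** (the reading center's grade of the same
single-field image the AI consumes). Referable DRD is ETDRS ≥ 35 or DME;
vision-threatening DRD raises the cut to ETDRS ≥ 53; center-involved DME is
OCT central-subfield thickness strictly greater than 300 µm. ETDRS modifier
letters (35A–35F, …) are retained for display and stratification but never
enter threshold logic: every published threshold is a bare base code, so
ordinality is defined on the base alone.

Participant-level aggregation is not something a publication typically
specifies, so the package fixes two conventions and names them:

- **Worst-eye rule** for reference positivity: a participant is positive if
  any eye is.
- **Any-diagnosable-eye rule** for the AI output: `detected` if any
  diagnosable eye is detected, `insufficient_quality` only when every eye is.
  This is the only aggregation under which participant-level diagnosability
  (95.8%) can exceed eye-level diagnosability (90.6%); a both-eyes-required
  rule is arithmetically incompatible with those two figures.

Missing optional fields (OCT thickness, Level II grade, AI output in the
reference fixture) are represented as absent values, never sentinels, and
operations that need them fail loudly naming the unit.

## The reference fixture

`paper_fixture.build_reference_dataset()` reconstructs the 1073-eye
analyzable set exactly at the level this package analyzes it: the published
ETDRS severity distribution (275 eyes at ≥ 35, 24 at ≥ 53), 43 DME eyes, 311
referable and 60 vision-threatening eyes, and 221 positive participants of
567. The printed totals force the DME allocation — 36 DME eyes below ETDRS
35, none in [35, 53), 7 at ≥ 53 — and the participant pairing (90
both-positive, 131 one-positive, 61 single-eye). Within-stratum placement,
demographics and thickness draws are not identifiable from the publication
and are fixed by an internal seed so the fixture is byte-stable. The shipped
`paper_eyes.csv` carries reference labels and demographics only; AI outputs
and Level II grades are deliberately absent (the device outputs are
proprietary), so AI-dependent analyses run on synthetic data instead.

## The synthetic generator

`SimulationConfig` defaults are the published marginals; two dependence
parameters are calibrated once, analytically, from printed figures:

| parameter | default | source |
|---|---|---|
| eye-level disease draw | Table of severity weights (545/1073 at level 10, …) | published distribution |
| DME given stratum | 36/798 below 35; 0 in [35,53); 7/24 at ≥ 53 | forced by totals |
| inter-eye severity correlation ρ | 0.5145 | solves ρp+(1−ρ)(2p−p²) = 0.3898 at p = 0.2898 |
| AI sensitivity / specificity | 0.796 / 0.884 | eye-level operating point |
| quality-failure rate q | 0.094 | 1 − eye diagnosability |
| quality-failure correlation θ | 0.3894 | solves 1−(θq+(1−θ)q²) = 0.958 |
| Level II grader sens/spec | 0.672 / 0.998 | reading-center performance |
| demographics, dilation, HbA1c, age | published Table-1 mixes | |
| OCT thickness (mean, sd) µm | 245/35 positive, 242/22 negative, 307/35 DME | published moments; DME component is a modeling choice so the center-involvement rule is exercised |

**Dependence mechanism.** Both inter-eye correlations use a shared-draw
mixture: with probability ρ (or θ) the two eyes share a single
(severity, DME) draw (or failure coin), otherwise the draws are independent.
This spans independence (ρ = 0) to comonotonicity (ρ = 1), is transparent,
and admits the closed-form calibrations above. Note the direction: a larger
failure correlation clusters failures, so participant-level diagnosability
under the any-diagnosable-eye rule weakly *decreases* in θ — from 0.991 at
independence to 0.906 at comonotonicity, with the 0.958 target between.

One random stream is spawned per participant (`SeedSequence.spawn`), so
inserting new fields or growing the trial never perturbs earlier
participants' draws.

**What the generator does not emulate:** images, operators, camera physics,
site effects, severity-dependent AI accuracy (sensitivity is one number
regardless of ETDRS level, whereas real detectors find severe disease more
easily), severity-dependent quality failure, and demographic effects on any
operating characteristic (subgroups differ only by sampling noise — which is
precisely what makes it a null model for the bias audit). Passing tests
therefore demonstrate the *statistical machinery* is calibrated, not that
any real device performs at these levels.

## Clustered bootstrap and non-inferiority testing

Replicates resample whole participants with replacement to the original
count; a replicate never contains one eye of a two-eye participant.
Optional **spectrum expansion** then appends resampled participants carrying
at least one ETDRS ≥ 53 eye until such eyes first reach the target fraction
(default 20%) of Level-I-positive eyes. Whole participants are appended —
rather than re-weighting eyes — because re-weighting would break cluster
semantics; the first-crossing rule makes the achieved fraction land in
[target, target + 1/n_pos].

Open mechanics were resolved as follows and are interpretations, not
reproductions of the original SAS analysis:

- **Lower bound**: empirical 2.5th percentile of replicate metrics (plain
  percentile method, no BCa) — the simplest estimator consistent with a
  one-sided 97.5% bound.
- **NI p-value**: add-one-smoothed bootstrap tail, (1 + #{p̂\* ≤ p0})/(B+1),
  one-sided. Smoothing keeps p > 0 at finite B and makes p monotone in the
  point estimate on fixed-margin families.
- **Degenerate replicates** (empty denominator) are excluded and counted; an
  error is raised past 10%.
- **Hierarchical testing** of secondary endpoints is fixed-sequence: test in
  the user-supplied order at full α, stop at the first failure.

Measured calibration at the default study conditions (567 participants, true
sensitivity 0.796), as computed by `tests/test_acceptance.py`: one-sided
97.5% lower-bound coverage within 2 Monte-Carlo standard errors of 97.5%
over 500 simulated trials, and study-level type-I error at the 75% null
boundary within α + 2 MC s.e. The percentile method is known to be slightly
anticonservative at these cluster counts; it stays inside the stated bands.

## Power simulation

The published design fixes eye counts (200 positive including at least 20 at
ETDRS ≥ 53, 140 negative) but not their pairing into participants. The
package's `DesignSpec` fixes a composition of 70 both-positive, 60
discordant and 40 both-negative clusters (170 participants, 340 eyes) with
20% of positive eyes severe — matching the ~20% severe fraction screening
populations show. At a true operating point of (0.85, 0.90) the simulated
study power exceeds 0.80, consistent with the design's power claim; the
published alternative hypothesis is unstated, so this is a property check,
not a reproduction.

## PAS and the break-even ratio

`pas` evaluates the exact expression; `pas_simplified` the equal-prevalence
product s·c·d (they agree to 1e-12 when p_c = p̂_nc, property-tested). The
break-even ratio divides the two systems' PAS at shared access; with equal
prevalences access cancels algebraically. Default prevalence is 0.2 for both
subpopulations — conservative, since prevalence is likely higher where
access is absent. The Monte-Carlo interval for the ratio draws each
sensitivity from a normal with s.e. inferred from its 95% CI half-width
(truncated to (0,1)); zero-width CIs collapse to the point ratio. The
propagation scheme behind the published interval is unstated; ours is
labeled an interpretation and its test asserts bracketing and symmetry, not
equality with the printed interval.

The risk lookup attaches fixed literature-derived outcome risks to the two
disease-level outputs (18.5% 3-year proliferative-retinopathy risk, ~11%/35%
1y/3y moderate-vision-loss risk for `detected`; ≤ 1.8% for `not_detected`)
and is deliberately a lookup — the package does not re-derive those trial
results.

## Bias audit

Subgroup contrasts default to the conventional two-level partitions (male vs
female, Black vs non-Black, Hispanic vs non-Hispanic; unknown attribute
values excluded). Each group's participants are resampled independently
(clusters intact); the two-sided p-value doubles the smaller smoothed tail of
the difference distribution, capped at 1, unadjusted for multiple
comparisons. Null calibration at the default study size is ~5% rejection at
nominal 0.05 (within 2 MC s.e. over 200 simulated null trials) — the test is
mildly anticonservative, like the primary percentile bootstrap. The
minimum-subgroup rule is total: a cell below `min_n` (default 10)
participants reports no estimate, difference, or p-value in any rendered
output.

## Numerical and engineering choices

- Metrics are exact ratios of integer counts; display rounding (one decimal
  percent) happens only at render time.
- Empty denominators raise `UndefinedMetricError`, never return 0.
- The bootstrap engine runs on per-participant count arrays extracted once
  per dataset; object-level `cluster_resample`/`spectrum_expand` are provided
  for composition and testing and agree with the array path by construction.
- All randomness flows from `numpy` `SeedSequence`s; the pipeline splits one
  global seed per stage so stages re-run independently and the full bundle is
  byte-identical under equal configuration.
- Validation sizes: 500 simulated trials at 400 bootstrap replicates for
  coverage/type-I, 200 trials at 300 replicates for the bias-audit null, 200
  trials for power — the package's default validation settings; production
  analyses default to 10,000 replicates.

## Known limitations

- The worst-case worked example's denominators (341, 830) sum to 1171, more
  than the 1073 analyzable eyes; the published fractions force the 65/43
  insufficient-quality split and carry a small rounding tension with the
  90.6% diagnosability figure. The package reproduces the printed arithmetic
  exactly and leaves the reconciliation to the source.
- Headline accuracy point values (79.6%, 88.4%, the printed p-values) are
  not reproducible without the proprietary trial data; the package instead
  validates its machinery on synthetic data with known truth.
- Single-eye participants occur in the reference fixture but the generator
  always produces two eyes; participant-level formulas do not depend on this.
- The Level II grader model is a conditional Bernoulli with fixed
  sensitivity/specificity; real grader behavior varies with severity.
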
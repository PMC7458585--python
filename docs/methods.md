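# Methods

## The rubric engine

The I-scale is an ordinal severity score for "infodemic monikers" — search
terms, queries or hashtags that feed misinformation, misinterpretation or
discrimination. Five categories (generic, misinformative, discriminatory,
deviant, other specificities) each receive 0–2 integer points from a human
analyst; the score is their sum and the severity class the interval it
falls in (0 / 1 / 2–4 / 5–8 / 9–10). Point assignment is a judgement call
that the engine deliberately does not automate: the computable contract is
validation (points in {0, 1, 2}, non-empty moniker, case-insensitive
uniqueness after trimming, since "corona" and "Corona" are one search
query), arithmetic, and classification. The five intervals partition
{0, …, 10}; this is asserted by an exhaustive test over all 3⁵ = 243
category combinations.

The bundled file `data/keyword_annotations_synthetic.csv` carries
per-category breakdowns for the bundled keyword tables. Only total scores
were ever published for those keywords, so these breakdowns are synthetic
reconstructions consistent with the rubric's worked rules (e.g. "COVID"
generic = 1, country names discriminatory = 1, "coronavirus laboratory"
misinformative = 2); their row sums match the published totals exactly,
which is what the tests pin.

## Search-volume statistics

**Normalization.** Raw counts map to integer RSV by
`round_half_up(100·v/max)`. Half-up rounding is used everywhere a display
value is produced (RSV integers, percentage shares, multiples), because the
upstream data source publishes integers and the reference tables were
rounded that way; Python's default banker's rounding would disagree on
ties. An all-zero series cannot be rescaled and is returned unchanged with
a `degenerate` flag.

**Windowed peaks and APC.** "Average peak volume" is operationalized as:
tile the date range into consecutive windows of `window_days` (default 7,
one Trends display week) anchored at the first observation, keep the
trailing partial window, take each window's maximum, and average per
geography. The APC total sums the per-geography means — which is why
published totals exceed the RSV ceiling of 100 — and the confidence
interval propagates the per-geography variance of the window peaks:
half-width `z·√(Σ_g s_g²/n_g)` with `s_g² = 0` when a geography
contributes a single window. The lower bound is floored at 0 (volumes are
non-negative). With printed estimates that carry only CI bounds, class-level
aggregation falls back from variance propagation to summing member bounds;
each class is tagged with the method actually used. The two conventions
genuinely differ and neither reproduces published class CIs exactly, which
is expected: those cannot be reconstructed from per-keyword totals alone.

Severity shares are reported against two denominators — all keywords, and
excluding the not-infodemic class — because published percentage summaries
are not consistent with a single one (1487/2888 = 51.5%, 1487/2834 =
52.5%).

**Breakouts, spikes, events.** Breakout = RSV exactly 100 (defined only
for normalized series). A spike is a strict local maximum at or above a
threshold (default 50); endpoints compare against their single neighbour,
so a monotone rise spikes at its last day and flat stretches never spike.
Event alignment matches each spike to the nearest event within
`tolerance_days` (default 2), ties going to the earlier event; unmatched
spikes and events are reported separately. Ranking is by descending APC
total with ascending lexicographic tie-break.

## Hashtag shares

Shares are always fractions of the provided table's grand total, never of a
platform-wide count, and tags are canonicalized (trim, strip leading `#`,
case-fold) before uniqueness checks. Two subset-combination conventions are
implemented because they disagree by a rounding step on real tables:
`sum_of_rounded` (add the 1-decimal display shares; the convention behind
published combined figures, and the default) and `exact` (round the exact
combined ratio). Counts are posts, not distinct users; the package reports
counts and shares and makes no user-level claim.

## Country-level association

Pearson's r is computed from the defining sums, t from
`r·√((n−2)/(1−r²))`, and the two-sided p-value from the Student-t tail
with n−2 degrees of freedom (the one step delegated to scipy). Degenerate
panels (n < 3, zero variance) are rejected. |r| = 1 short-circuits to
p = 0 to avoid dividing by zero. p-values are kept at machine precision and
displayed as "<.001" below that threshold. The panel builder inner-joins
per-country series with an incidence table and makes the interest measure
explicit — window-mean RSV by default, or the per-country APC total —
because correlation reports rarely state which summary entered them.

## Synthetic generators

What they emulate: Trends-like daily series over the 77-day study window
(2020-02-20 to 2020-05-06) as baseline + triangular spike kernels
(default half-width 5 days, chosen so the argmax is analytic and
spike-detection tests can be exact) + Gaussian noise floored at 0; hashtag
tables as one multinomial draw; country panels as bivariate lognormals.
Defaults are the study conditions: baseline 10, noise sd 3, spikes of
magnitude 40 (day 34) and 90 (day 57) mirroring a mid-window story and a
late dominant event; 40-country panels with observable correlation 0.45.
Every generator is a pure function of (scenario, seed); the default seed
20200220 encodes the study start date.

What they do not emulate: the sampling jitter of repeated Trends
extractions, weekly-vs-daily resolution changes, long-memory autocorrelated
baselines, or platform-specific tag dynamics. Passing recovery tests
therefore demonstrates estimator correctness under clean conditions, not
robustness to those artefacts.

**Panel transform and calibration.** Exponentiating a latent bivariate
normal pair (unit variances, correlation ρ) gives right-skewed positive
panels like real incidence data, but shrinks the observable correlation to
the lognormal closed form (e^ρ−1)/(e−1) — verified here against
large-sample simulation — and roughly doubles the sampling sd of the
Pearson estimate relative to the Gaussian value (1−r²)/√n. The generator
therefore reports the realized correlation as its ground truth, and offers
`transform="normal"` (an affine shift into positive support, correlation
preserved exactly) for tests whose tolerances are derived from Gaussian
sampling theory: the 2,000-country recovery check uses the normal
transform with the 3σ band ±0.054, while the lognormal calibration is
checked at n = 100,000 with a 4σ band (±0.03; σ ≈ 0.0066 measured over 30
seeds). Lognormal pairs cannot reach correlations below (1/e−1)/(e−1) ≈
−0.37; the inverse calibration rejects unreachable targets.

**Monte-Carlo sizes.** Coverage uses 1,000 replicates of 100 N(50, 5)
window peaks (the large-sample z-interval is nominal to well within the
93–97% acceptance band at n = 100); width scaling averages 300 replicates
at n ∈ {25, 100, 400}; null calibration uses 2,000 replicates of 40-country
null panels, where the t-based p-value is exactly uniform under normality.

## Pipeline and report

`run_pipeline` composes the stages; any input path left unset falls back to
the bundled tables (and the synthetic panel generator for the
association), so the default run reproduces the headline numbers with no
external data. Failures are tagged with the stage name and no partial
output bundle is left behind. The JSON report has fixed section order
(`meta, iscale, apc, severity, hashtags, association, raw`), display
rounding (shares 1 decimal, r 2 decimals) with full-precision values under
`raw`, and is byte-identical for identical config + seed.
`validate_report` enforces the required sections structurally.

## Known limitations

* The APC definition (7-day anchored windows, sum over geographies) is one
  defensible operationalization; published APC values from proprietary
  extracts are not desk-reproducible, so the estimator is validated by
  Monte-Carlo recovery rather than by matching printed point estimates.
* Severity-class CIs from printed per-keyword bounds are approximations;
  variance propagation needs the raw window peaks.
* The correlation module does no confounder adjustment, regression
  modelling, or spatial autocorrelation handling — it answers exactly one
  bivariate question.
* Rubric scoring is only as good as the human annotations it validates.
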
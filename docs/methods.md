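# Methods

## Data model

The unit of input is one participant-week of epoch-level acceleration
magnitudes in milli-gravity units (mg, 1/1000 of standard gravity). An
epoch is a fixed summary window of the wrist signal — 5 s in the cohorts
this pipeline targets, giving 168 × 720 = 120,960 slots per week — and the
magnitude is the gravity-removed Euclidean norm of triaxial acceleration
computed upstream; this package never touches the raw 100 Hz signal.
Blank epochs are represented as NaN, and a boolean flag per epoch records
whether its value was imputed rather than measured (either by the upstream
provider or by this package's daylight-saving repair). All downstream code
works from epochs-per-hour = 3600 / epoch_seconds, so coarser epochs
(60 s, 300 s) run the identical logic at lower cost.

## Quality grades and daylight-saving repair

Weeks are graded by slot count and blank structure:

| grade | slots (5 s) | structure |
|---|---|---|
| complete, perfect | 120,960 | no blanks, no imputation flags |
| complete, imputed | 120,960 | no blanks, ≥ 1 flagged epoch |
| recoverable | 120,960 | exactly one blank epoch |
| spring DST | 121,680 | ≥ 720 consecutive blanks (the lost clock hour) plus one extra trailing hour |
| autumn DST | 120,240 | one hour short (the doubled clock hour collapses) |
| unusable | anything else | dropped |

The two DST grades are repaired to complete weeks: the missing hour is
filled epoch-wise with the mean of the same clock hour on the other six
days (spring additionally drops the extra trailing hour), and every filled
epoch is flagged imputed. Same-clock-hour imputation is exact for any
pattern that repeats daily at that hour; because the transitions fall in
night hours, where weekday/weekend differences are small, the residual
error is confined to the one imputed hour and is fractions of a mg on the
synthetic archetypes.

## Exclusion funnel

The funnel removes, in order: participants withdrawn from the study,
participants outside the 40–69 baseline age range (both read from a
metadata table, never inferred from the signal), unusable-quality weeks,
and finally — jointly — weeks whose mean over valid epochs is ≥ 100 mg and
weeks with under 72 h of non-imputed wear. Non-imputed wear is counted at
the epoch level: valid, unflagged epochs × epoch length. The two
suitability filters are applied jointly with both reason codes recorded,
so an overlapping participant is counted once in the funnel but appears
under both reasons; the report asserts exact count conservation
(supplied = retained + all exclusions) on every run. The mean filter uses
≥ 100 mg (inclusive); the wear filter is strict (< 72 h), so exactly 72 h
is retained.

## Hourly aggregation and week alignment

Hourly values are means over the valid epochs of each hour (a recoverable
week has one hour averaged over 719 rather than 720 epochs); an hour with
no valid epochs is an error, which cannot occur after repair. Profiles are
rotated to a canonical week with index 0 = Monday 00:00 using the
recording's start weekday, because the weekly patterns of interest
(commute spikes, weekend bursts) are day-of-week phenomena; alignment can
be disabled (`preprocess_cohort(..., align=False)`) for analyses that
prefer wear-start-relative weeks.

Report percentages round half-up (away from zero) to one decimal, or to
whole percents where tables print whole percents; differences are computed
on unrounded values and rounded last.

## Distances

The clustering metric is the plain (not squared) Euclidean distance
between 168-hour profiles, which damps the influence of outlying profiles
relative to squared-distance criteria. Dynamic time warping is provided as
the alternative elastic metric: classical DTW with absolute-difference
local cost, unit match/insert/delete steps, no path-length normalisation,
and an optional Sakoe–Chiba band (default: no band, i.e. unconstrained
warping). The agreement between the two metrics is summarised as the
Spearman rank correlation of the vectorised upper triangles of the two
distance matrices over a seeded subsample of profiles — a rank statistic,
because the substantive question is whether the two metrics *order* pairs
the same way. Profiles are not standardised before distance computation:
intensity differences between patterns are part of the signal.

## k-medoids

`fit` implements classical PAM. BUILD greedily seeds k medoids (first the
point minimising total distance to all others, then repeatedly the point
with the largest dissimilarity reduction); SWAP repeatedly applies the
single medoid/non-medoid exchange with the most negative cost change until
none improves. Each accepted swap strictly decreases the total
dissimilarity (a 1e-12 relative guard prevents floating-point cycling),
and the per-swap cost history is stored on the solution so monotonicity is
assertable. Assignments are nearest-medoid with ties to the lowest medoid
index. The default is best-of-three initialisations — the deterministic
BUILD start plus two seeded random medoid sets — which on random small
instances attains the exhaustively enumerated optimum in ≈ 99/100 cases
(single-start BUILD+SWAP, like the canonical R implementation it was
cross-checked against, stalls in local optima a few percent of the time).
For cohorts too large for the n × n distance matrix, `fit_clara` fits PAM
on seeded subsamples (size 40 + 2k by default) and keeps the candidate
medoid set that scores best on the full data.

## Choosing k

`scree` fits every k in [k_min, k_max] with a shared seed policy so the
curve is comparable across k, and each k also warm-starts from the
previous k's medoids extended by the best additional point — adding a
medoid never increases cost, so the curve is non-increasing by
construction. The suggested k formalises "the last sizeable drop": with
first differences Δ(k) = D(k−1) − D(k), the rule picks the largest k such
that Δ(k) > (1 + τ) × median(Δ(k+1), …, Δ(k_max)), with τ = 0.5 by
default; the final k has no tail to compare against and is never
suggested, and a flat curve suggests k_min. The median of the remaining
tail is a robust estimate of the plateau reduction rate, and τ sets how
far above that plateau a drop must stand to count as sizeable.

## Profiling tables

Composition tables report, per cluster (or per sample, for selection-bias
checks), the percentage of participants with each binary characteristic;
missing responses are excluded from both numerator and denominator of
their cell, with per-cell denominators recorded in the output. Row
extremes (max and min across cluster columns, ties all marked) are
computed on unrounded values. Outcome difference tables give, within each
outcome category, the percentage distribution across clusters and its
difference from the overall cluster shares; rows therefore sum to 100 and
differences to ~0 up to rounding. The survival/testing summary uses the
reporting denominators: alive % of the cluster, tested and positive % of
those alive, positivity % of those tested, with positivity undefined (not
zero) when nobody was tested. Cluster display names are user-supplied
metadata; the package never auto-labels patterns.

## Synthetic cohorts

The generator emulates the study conditions the pipeline is built for.
Nine archetypal weekly patterns are parameterised as a resting base level
plus Gaussian bumps (day, hour, amplitude, width) and an optional weekend
multiplier, with amplitudes in the hourly mg range seen on wrist data
(night 6–12 mg, day 15–70 mg): a commuting "active_9to5" with 08:00 and
17:30 spikes, "active" without the evening spike, a fading
"morning_movers", "get_up_and_active" with a morning spike over a moderate
plateau, "live_for_weekend" with weekday plateau and weekend peaks,
featureless "moderates", a half-amplitude "leisurely_9to5", a low fading
"sedate", and a flat "inactive".

Epoch noise is Gaussian, truncated at 0 mg, with standard deviation
scaled by local activity level — sd = noise_sd × (0.5 + level/mean) — so
active hours are noisier, as on real accelerometry; the default
noise_sd = 30 mg at 5 s epochs leaves hourly standard errors of ~1–3 mg.
A zero-noise series re-aggregates to its template exactly, which anchors
the pipeline's round-trip tests.

The default cohort is 100 participants per archetype (900 in total) at
5 s resolution with start days uniform over the week, plus three constant
~150 mg outlier weeks and five participants with 100 h of flagged epochs
(68 h of measured wear) destined for exclusion. Completeness scenarios are
assigned per participant in proportions mirroring large-cohort experience
(≈ 24% pristine, 49% upstream-imputed, 23% one trailing blank, 1.2%
spring-DST, 2.2% autumn-DST); a scattered-gap scenario that renders weeks
unusable is available but off by default so the default cohort retains
exactly 900. All randomness derives from one integer seed through spawned
generators, making cohorts byte-reproducible.

What the generator does *not* emulate: device calibration error, non-wear
episodes that must be detected from the signal, autocorrelated
within-hour noise, seasonal and weather effects, and the continuous
between-participant variation of real cohorts (participants are noisy
copies of nine discrete templates). Passing recovery tests therefore shows
the pipeline is correct and that the k-selection rule behaves as intended
when distinct patterns exist; it does not show that nine clusters — or any
particular k — is the right description of a real population.

## Problem sizes and determinism

The bundled analyses run on one CPU in seconds to a couple of minutes: the
default 900-participant cohort is generated and preprocessed streamingly
(one 120,960-epoch series in memory at a time), the scree spans k = 1…16
on the 900 × 168 matrix, metric agreement uses a 40-profile subsample
(780 pairs), and the optimality spot-checks use 100 random instances with
n ≤ 7 against exhaustive enumeration and 200 short-vector DTW pairs
against explicit path enumeration. Every entry point takes a seed and is
deterministic given it; text outputs are byte-identical across runs.

## Known limitations

- The k-selection rule compares each drop only against the plateau that
  follows it; curves whose reductions decay smoothly with no plateau
  (no real cluster structure) correctly fall back to k_min, but curves
  with several well-separated scales may warrant inspecting the scree
  directly rather than trusting a single suggested k.
- Same-clock-hour DST imputation biases the filled hour toward the
  weekly mean of that hour; for night transitions this is negligible,
  but the repair would be cruder for hypothetical daytime gaps.
- PAM is a local search; even with restarts the global optimum is not
  guaranteed. CLARA trades further optimality for memory.
- The epoch file format stores timestamps at a fixed UTC offset;
  daylight-saving structure is inferred from slot counts and blank runs,
  not from timezone arithmetic.
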
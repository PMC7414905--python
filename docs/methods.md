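# Methods

This note documents the models, rules and numerical choices behind
`thermoniche`, and what the synthetic-data generator does and does not
emulate.

## The measurement model

A tethered dung beetle is flown in front of a thermal infrared camera.
Three fixed 3x3-pixel regions of interest (ROIs) are read per frame — thorax
(metathoracic plate), abdomen (third abdominal sternite), nearby background —
and each ROI contributes its **maximum** pixel per frame. The maximum, not
the mean, is used because a leg sweeping through the window reads cooler
than the flight muscles and would bias a mean downward. ROIs are static;
re-centering on a moving body part is out of scope and the limitation is
inherited by any real recording in which the animal drifts more than a pixel.

Apparent temperatures are converted to surface temperatures with a
single-reflection greybody model on T^4 radiance (Kelvin):

    W_obj = (W_meas - (1-eps) * tau * W_refl - (1-tau) * W_atm) / (eps * tau)

with emissivity `eps` in (0, 1] and atmospheric transmittance `tau`
defaulting to 1 (at 0.5 m working distance atmospheric absorption is
negligible). This is the standard thermography correction consistent with
correcting "by reflection, relative humidity, distance and emissivity"; the
exact vendor formula is proprietary, so the package documents and tests its
own inversion (forward model composed with the correction is the identity to
1e-8 for any emissivity). Cuticle emissivity is estimated against a
reference emitter of known emissivity (electrical tape, eps = 0.95) held at
the same set-point temperatures (50-80 degC), as the no-intercept
least-squares slope of background-subtracted radiances; the estimator
recovers a planted emissivity to 4 decimals at zero noise. By default only
thorax and abdomen traces are corrected; the background ROI is not a
greybody of known emissivity (a flag overrides this).

Only flights with >= 40 s of continuous flight after take-off are analysed.
When no take-off annotation is available, take-off is detected at the
largest forward difference of the thorax trace — a step/warm-up signature —
which recovers a planted take-off to within one frame on step-like onsets
but is only a heuristic for gradual warm-ups.

## Thermal-niche variables

* **Endothermy (excess temperature)**: mean of (T_th - T_env) over the
  flight window. Shift-invariant by construction.
* **Slopes sT_th, sT_abd, sT_env**: ordinary-least-squares slopes of each
  trace over [take-off, take-off + 40 s]. The window end is configurable;
  samples beyond it never enter the fit.
* **Slope difference** sT_th - sT_abd: an index of heat *not* transferred
  from thorax to abdomen.
* **Minimum tethered flapping temperature** (pipeline output
  `takeoff_temp`): the thorax temperature at take-off.

## Thermoregulation-mechanism rule

Per species, the per-individual slope samples are compared with
tie-corrected Kruskal-Wallis H tests (df = 1 for a pair); "similar" means
P >= alpha with alpha = 0.05 by default. Mechanisms:

| call | th vs abd | mean sT_th | mean sT_abd | abd vs env |
|------|-----------|------------|-------------|------------|
| APHT | different | > 0 | — | similar |
| AAHT | similar | > 0 | > 0 | different |
| UNDEFINED | anything else | | | |

Sign is the sign of the species mean of individual slopes with threshold
exactly 0. If every slope value in a pair is identical, H is undefined; the
package reports H = 0, P = 1 (trivially similar) and logs the event. Note
that field descriptions of AAHT-like individuals sometimes report abdomen
and environment slopes as similar, which contradicts the formal AAHT
definition; the formal definition (abd vs env *different*) is implemented,
and only a species-level classifier is provided — no individual-level
criterion is defined.

The exact size of the chi-square-approximated Kruskal-Wallis test at
n = 10 vs 10 is 0.0524, so even with an arbitrarily strong planted effect a
planted APHT/AAHT species is recovered with probability ~ 1 - size ~ 0.95:
the "similar" leg of each rule fails at the test's own false-positive rate.
This is an inherent property of the rule, not an estimator defect.

## Habitat affinity and daily activity

IndVal uses the canonical Dufrene-Legendre definitions: specificity
`A_ij` = (mean abundance of species i over sites of habitat j) / (sum of
those means over habitats), fidelity `B_ij` = fraction of habitat-j sites
occupied, IndVal = A * B * 100. (Verbal paraphrases of A and B in the
applied literature are sometimes inconsistent with any statistic bounded by
100; the canonical formulas are implemented.) Significance permutes the
site -> habitat assignment; each species' null statistic is its maximum
IndVal over habitats and the p-value uses the add-one estimator with 999
permutations by default. Categories: indicator (IndVal > 70, strict, and
P < 0.05), detector (45 <= IndVal <= 70, closed band, P < 0.05), else none.
Species with zero total abundance have undefined specificity and are
reported as IndVal 0 / none, with a log message.

Daily activity: captures are binned by local clock into half-open periods
[7:00, 18:00) and [18:00, 7:00) (the second spans midnight); a species is
diurnal (or ENC) when >= 60% of captures fall in the respective period.
Species with fewer than `min_captures` captures (default 25 — the fallback
threshold is a package choice, as no standard value exists) or with neither
period reaching 60% fall back to a literature label when one is supplied.

## Microclimate

Sensor logs (5-min interval, 12 days by default) are partitioned by the same
7:00/18:00 boundary. Thermal amplitude = day maximum - night minimum,
computed record-wide by default (matching the parenthetical definition "the
maximum temperature during the day minus the minimum temperature during the
night for the 12 days"); a per-day-then-average variant is available via
`per_day=True` and is never wider than the record-wide value.

## Comparative statistics

Each response is modelled as

    response ~ habitat * activity + mass + (1 | species)

by REML (statsmodels `MixedLM`), with sum-to-zero contrasts so that
type-III Wald chi-square tests (`b' V^-1 b` per term) are meaningful.
Endothermy is log-transformed; non-positive endothermy values cannot enter
the log response and are dropped with a logged count. Singular fits
(random-intercept variance collapsing to zero) warn rather than fail; in
balanced designs the fixed effects then equal ordinary least squares, which
is the oracle used in tests.

Post-hoc cell contrasts use estimated marginal means at the mean of the mass
covariate, with studentized-range (Tukey) adjustment within each family
(habitats within an activity, or activities within a habitat) and
large-sample (normal) denominator degrees of freedom — small-sample
denominator-df corrections (Satterthwaite/Kenward-Roger) are not applied, so
with species-level factors and few species both the Wald chi-square tests
and the contrasts are anticonservative; the calibration suite therefore
checks the nominal level in the regime where the asymptotics apply
(residual-only noise, 30 species).

Body mass comparisons use tie-corrected Kruskal-Wallis plus Conover-Iman
pairwise post-hocs: t = (Rbar_i - Rbar_j) / sqrt(S^2 (N-1-H)/(N-k)
(1/n_i + 1/n_j)) on N-k df, with pooled tie-corrected rank variance S^2.
P-values are unadjusted by default — mirroring an explicit
no-multiplicity-correction stance across these hypotheses — with an
optional Holm flag. Pearson correlations are provided for the slope
variables that enter more than one hypothesis.

## The synthetic-data generator

The generator's defaults encode the study conditions the pipeline targets:
3 habitats x 3 sites, 5-day two-period capture sampling, 12-day 5-min sensor
logs, >= 40 s flights at 25 Hz (a typical thermal-video rate; the true frame
rate of any given camera is a config value, not an inferred fact), take-off
at 5 s, ambient 25 degC. The default species pool mirrors a published
17-species summary table bundled with the package (per-species mass,
endothermy, slope means and slope-pair test outcomes), so a full synthetic
run reproduces the bookkeeping of that community (17 species, 7 diurnal,
10 ENC; 5/8/4 species across native forest / agroforestry / open pasture).

Flight traces are built as: environment = base + optional drift + i.i.d.
Gaussian frame noise (0.3 degC by default); thorax = environment +
endothermy * (1 - exp(-warmup_rate * t)) + slope * (t - takeoff) after
take-off; abdomen likewise with a mechanism-dependent fraction of the
thoracic excess (0.1 for APHT — abdomen near ambient; 0.8 for AAHT —
abdomen tracks thorax; 0.35 otherwise). Warm-up is exponential saturation
(rate 0.5 /s) preceding the linear flight phase. Frame stacks embed the
traces as disjoint 3x3 patches whose center pixel carries the exact trace
value (so a <= 1 px patch jitter is absorbed by the max-over-window
extraction rule) on a background at the environment temperature.
Abundances are negative-binomial (gamma-Poisson, size 5) around planted
per-habitat means; captures are binomial between periods and uniform within;
sensor logs are a cosine diel cycle peaking at 13:00 plus noise. Every
generator takes a seed and emits a truth sidecar with the exact parameters
used.

What the generator does **not** emulate — and hence what green tests do not
show about real data: between-individual biological variation in slopes and
endothermy (synthetic slope scatter is pure measurement noise, so synthetic
slope tests are *more* powerful than field data at the same n — planted
slope differences of a few 1e-3 degC/s that are non-significant in the
field become significant here); radiometric raw counts and vendor
calibration; moving ROIs / tracking; temporal autocorrelation in traces and
sensor noise; overdispersed capture schedules; weather fronts in sensor
logs. Tests against the generator validate the estimators and rules, not
field effect sizes.

## Problem sizes used in the validation suites

Calibration suites use 500 species-replicates at 999 permutations for the
IndVal null, 500 simulated datasets (30 species x 8 individuals) for the
type-III interaction type-I error, 100 planted species per mechanism for
mechanism recovery, and 200 simulated flights for endothermy-recovery error
bounds; these sizes give binomial/Monte-Carlo standard errors comfortably
below the tolerance of each assertion while keeping the default test run
fast.

## Known limitations

* The take-off heuristic is crude for gradual warm-ups; supply annotations
  when available.
* The Wald/Tukey machinery is asymptotic (see above); with ~17 species the
  printed P values of any real analysis will differ from small-sample
  corrected ones.
* The IndVal permutation p-value is granular: with 9 sites in 3 equal
  groups, the smallest achievable p for a perfect indicator is ~1/28 plus
  permutation noise, so significance at alpha = 0.05 needs enough
  permutations (the 999 default is ample; demo runs at 199 can flip
  borderline species).
* Mechanism recovery is capped near 1 - alpha per species by the rule's own
  "similar" legs (see above).
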
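# Methods

This note records the scientific and numerical conventions the package
commits to, the design choices that were genuinely open, what the synthetic
generator does and does not emulate, and the problem sizes the checks run
at. Everything quantitative stated here is computed by the test suite, the
analysis scripts, or `scripts/acceptance.py`.

## Time, intervals, and units

All event times are float hours on a shared clock (the IO layer serialises
ISO-8601 UTC and parses back); every interval is half-open `[start, end)`.
Durations are decimal hours, MAP is mmHg, doses are µg/kg/min on the
norepinephrine-equivalent scale. Breakpoint coincidence is judged at 1e-9 h,
far below the minute granularity of charted data.

## Episode detection on irregular readings

The exposure is the longest continuous episode with MAP strictly below a
threshold while on vasopressor support. Charted MAP is a point process
(~hourly, irregular), so "continuous" requires a convention; the package
adopts **carry-forward**: a reading defines the state until the next
reading, or until a maximum carry-forward gap (`max_gap_hours`, default
1.5 h) elapses, whichever is first. Beyond the cap the state is undefined
and any running episode breaks — a deliberate conservative choice: long
charting gaps can never inflate an episode. The 1.5-h default sits above the
99th percentile of inter-reading gaps in dense ICU charting (and well above
the generator's 15–90-min gap distribution), so it only fires on genuinely
sparse stretches. An episode therefore runs from the first below-threshold
reading to the first subsequent at-or-above reading, clipped to the merged
vasopressor-support intervals (partial overlap counts only the overlapping
part; support intervals that touch are continuous support). Inequalities are
strict everywhere ("below 65" means < 65). Simultaneous duplicate readings
are averaged; values outside a plausibility window (10–250 mmHg, config-
urable) are dropped as artefact and counted.

Because the convention is a modelling choice, it is isolated in
`map_state_function`, and its correctness (not its clinical truth) is
checked exactly against a dense 1-minute-grid brute-force oracle on
randomized stays. The alternative reading (interpolation between readings)
would change per-stay durations by at most one inter-reading gap; the
sampling-consistency test quantifies exactly this kind of discretisation
error by comparing recovered durations with the latent path truth as the
sampling interval shrinks.

A stay whose only below-threshold reading is its final one has a
below-threshold exposure with zero measurable run length; it is assigned the
lowest exposed bin rather than the never-below reference, so "ever below"
and the bin labels never contradict each other.

## Vasopressor dosing

Conversion factors to norepinephrine equivalents ship as configurable data,
not code constants (equivalence tables differ slightly across sources):
norepinephrine 1, epinephrine 1, dopamine 1/100, phenylephrine 1/10 (all per
µg/kg/min), vasopressin 2.5 µg/kg/min per U/min. Rates charted in µg/min are
divided by baseline body weight; the vasopressin factor is already on the
per-kg-equivalent scale, so no weight enters (unit conversions are exercised
in tests, e.g. 0.04 U/min → 0.10 µg/kg/min). Weight is the baseline value;
no dynamic weight updates.

The high-dose rule (NED ≥ 0.2 µg/kg/min over any 6-h period) is read as
**sustained**: the summed step function stays at or above the level
continuously for the span. A windowed alternative (some 6-h window whose
time-weighted mean reaches the level) is implemented behind `mode=
"windowed"`, since the phrase admits both readings; sustained is the default
because it matches the package's continuous-episode framing. The sustained
rule is monotone in rates and durations (property-tested) and implies
max-NED ≥ level.

## Cohort rules

Rule order is fixed (age; continuous support ≥ 6 h; exclusion codes; RBC
volume; charting gaps; multiple qualifying stays) so exclusion ledgers are
comparable across runs; the rules are conjunctive, so order affects per-rule
counts but never membership (tested by re-deriving membership per stay).
Notable operationalisations:

* *Continuity of support*: infusion intervals are unioned across the five
  drugs and merged across gaps ≤ 15 min (configurable) — pump swaps and
  charting seams routinely fragment a clinically continuous infusion.
  The ≥ 6 h bound is closed.
* *Charting-gap exclusion*: no interval > 24 h (configurable) without a MAP
  reading between ICU admission and discharge, including the leading and
  trailing edges; a stay with no readings is excluded. The underlying
  clinical concept ("gaps in the stay data") has no canonical definition;
  this one is explicit and conservative.
* *RBC exclusion*: ≥ 3500 mL in any 48-h window, closed at both ends; since
  the maximising window can be anchored at an event, scanning event-anchored
  windows is exact (verified against an exhaustive pair scan).
* *Code matching* is exact string equality on dot-stripped codes within a
  type (diagnosis / procedure / DRG); no hierarchy expansion.
* *ICU death*: a death date within 24 h after ICU discharge (closed bound);
  date-only death records are treated as midnight timestamps upstream of
  this package. The 28-day sensitivity outcome is any death within 672 h of
  ICU admission.

## Estimands

Wilson score intervals are computed in closed form; the k = 0 and k = n
bounds are exactly 0 and 1. The per-2-h mortality trend is an n-weighted
least-squares slope of bin mortality on bin midpoint over exposed bins
(never-below excluded; bins with n = 0 dropped; the open-ended ≥ 20 h bin
gets midpoint 22 h = lower edge + half the preceding bin's width). The
dichotomous < 2 h group excludes never-below stays by default (a switch
includes them); both choices are defensible readings of "longest episode
< 2 h" and the package makes the toggle explicit rather than silently
picking one.

## Regression

Reference-cell dummy coding with fixed references (never below; dose
0–<0.2; age < 65; male; SOFA ≤ 4; labs in range; no flag). Missingness in
baseline MAP, albumin, creatinine and lactate is an explicit modelled
category — never imputed, never dropped. Estimation is Newton maximum
likelihood (statsmodels) with relative tolerance 1e-10 and ≤ 100 iterations;
inference is Wald (the estimate/SE/chi-square/p/OR layout standard in this
literature). Degenerate outcomes, perfect or quasi-separation (diverging
estimates with a flat likelihood), and rank-deficient designs raise typed
errors; orchestration-level callers (threshold sweep, sensitivity suite,
pipeline) report such models as unavailable instead of emitting meaningless
odds ratios — at a few thousand stays the sparsest dose and duration cells
can be all-death or all-survivor, and that is surfaced, not smoothed over.
Sparse cells are never pooled. Predicted marginal mortality is
standardisation: every stay is counterfactually assigned the category and
predictions are averaged over the observed covariate distribution.

The test suite cross-checks coefficients and standard errors against an
independent from-scratch IRLS solver (1e-8 agreement) and the Wilson
interval against numeric inversion of the score equation (1e-10), so the
library dependency is never its own oracle.

## The synthetic generator

What it emulates: per-stay latent MAP as a stationary AR(1) process on a
1-minute grid (default per-minute autocorrelation 0.97, innovation SD
2 mmHg → stationary SD ≈ 8 mmHg, baseline uniform in 70–88 mmHg); planted
hypotension dips (soft-edged negative excursions during support, default
probability 0.7, depth 10–35 mmHg, lognormal duration with median 3 h) so
exact ground-truth durations exist; jittered reading times (mean 47.5 min,
SD 12, clipped to 15–90); multi-drug infusion records with piecewise rates,
mixed units, and occasional sub-tolerance record splits; independent planted
exclusion triggers at ~1 % rates each; covariates with marginals typical of
a large distributive-shock cohort (age 66 ± 16, ~47 % female, ~70 % septic,
SOFA 7.4 ± 3.8, realistic lab missingness including ~58 % missing albumin);
and mortality drawn from a planted logistic model whose default coefficients
span the scale reported for such cohorts (duration log-odds 0.57 → 1.96,
intercept −3.39).

Two deliberate design points:

* **The outcome conditions on the recovered exposure.** The planted model
  uses the duration bin computed from the *sampled readings* (exactly what
  the regression will later see), not the latent-path truth. Downstream
  estimation is therefore consistent for the planted coefficients; the
  latent truth is still recorded so the sampling-error properties can be
  tested separately (recovered durations converge to truth as the sampling
  interval shrinks).
* **A design-level replicate sampler** draws duration bins, covariates and
  outcomes directly from the planted model, skipping the waveform layer.
  The replicated recovery experiment (100 replicates × n = 20 000) runs on
  this sampler: the quantity under test is estimation, and the waveform
  machinery would add only runtime, not information. The waveform path is
  exercised end to end in its own tests and in the acceptance script.

For the recovery experiment the planted ladder is evenly spaced from 0.57
to 1.96 (strictly increasing, adjacent gap ≈ 0.174), allocation is 10 %
never-below and the rest equal across the nine exposed bins, and the
intercept (−1.50) centres exposed-bin death probabilities near 1/2 after the
mean covariate contribution. These choices come from a power calculation:
recovering the *ordering* of nine coefficients requires each adjacent gap to
exceed its sampling noise (SE of an adjacent difference ≈ 0.067 under this
design, giving ≈ 0.5 % inversion probability per pair); near-tied planted
values would make ordering recovery impossible at any reasonable n.

An optional severity term (extra death log-odds per hour of the longest
episode below 55 mmHg, default off) plants depth-dependent risk; with it
on, the mortality-duration trend slope steepens monotonically as the
threshold deepens from 80 to 55 mmHg, and the acceptance suite asserts that
ordering.

What it does **not** emulate: physiology beyond second-order statistics
(no circadian structure, no treatment feedback loops, no correlation
between vasopressor dose and MAP trajectory), waveform-level artefact
structure, informative charting (sicker patients charted more often), or
death as a time-to-event process truncating the stay. Passing tests
demonstrate that the pipeline's algorithms are correct and its estimators
recover planted truth — not that the clinical associations would replicate
in real data, where immortal-time bias (long episodes require surviving
long enough to accrue them), unmeasured severity, and the sensitivity/
specificity of the shock definition all remain.

## Determinism and problem sizes

A fixed seed fully determines all generator output (one spawned RNG stream
per table; rerunning a pipeline config is byte-identical, checked by
hashing). The default test run uses ~1000 randomized stays for the grid-
oracle equivalence checks, cohorts of a few hundred to a few thousand stays
for pipeline-level tests, and 100 × 20 000 for the recovery experiment —
sizes chosen so the full suite completes in about a minute on one CPU while
keeping Monte-Carlo error well inside the asserted margins. The analysis
scripts default to 3000 raw stays; the acceptance script runs the
end-to-end pipeline at 8000.

## Known limitations

* The carry-forward convention is one defensible reading of "continuous";
  results on real data would be somewhat sensitive to it (the config
  exposes the cap, and the sampling-consistency test bounds the effect).
* The high-dose rule's sustained-vs-windowed ambiguity is resolved by
  configuration, not evidence.
* Separation handling reports models as unavailable rather than switching
  to penalised likelihood; a Firth-type fallback would be a natural
  extension.
* The exclusion-code lists are literal defaults for the synthetic data;
  real deployments must supply their own configured lists.
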
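# Methods

## Measurement model and analysis chain

A head-fixed mouse receives a sinusoidal vestibular (turntable) or visual
(optokinetic drum) stimulus, velocity `s(t) = A sin(2πft)` with A = 10 °/s
and f = 1 or 0.5 Hz. The slow-phase eye movement is modelled as a sinusoid at
the stimulus frequency with gain g and phase φ, on which saccades and
movement artifacts (brief, high-velocity) and sensor noise are superimposed.
The analysis chain estimates g and φ from eye position:

1. **Low-pass filtering.** 4th-order Butterworth, 15 Hz cutoff, on position.
   Applied zero-phase (forward–backward) by default so that fitted amplitude
   and phase do not inherit filter lag; the trade-off is that the effective
   magnitude response is the square of the single-pass response (−6 dB at
   cutoff instead of −3 dB), which is irrelevant at the 0.5–1 Hz stimulus
   frequencies (single-pass attenuation at 1 Hz is < 10⁻⁹). A causal
   single-pass mode is available (`FilterSpec(zero_phase=False)`).
2. **Differentiation.** Savitzky–Golay derivative with a 30 ms window
   (31 samples at the 1 kHz default rate). Polynomial order defaults to 3:
   the symmetric quadratic-fit derivative attenuates a sinusoid of angular
   frequency ω by ≈ (ωh)²/10 (h = half-window), which is ~0.1% at 1 Hz —
   right at the pipeline's own recovery requirement — whereas the cubic-fit
   derivative is accurate to O((ωh)⁴) (~10⁻⁵) with essentially identical
   noise amplification through the 15 Hz-filtered chain (0.30 vs 0.32 °/s on
   integrated 2 °/s velocity noise). Order 2 remains available.
3. **Two-pass sinusoid fit.** Pass 1 is an ordinary least-squares fit of
   `c + a sin(2πft) + b cos(2πft)` (linear in (c, a, b); amplitude √(a²+b²),
   phase atan2(b, a)) over all analyzable samples. Residuals exceeding
   31 °/s in magnitude (strict inequality) mark saccades/artifacts; each
   marked run is dilated by 50 ms on both sides, overlapping windows merge,
   and retained runs shorter than 10 ms are discarded as well. If the
   excluded fraction exceeds 45% (strict) the test is invalid and carries no
   amplitude. Otherwise pass 2 refits on the retained samples; its amplitude
   is the response measure. Exactly two passes — no iterative rethresholding.

**Interpretation choices.** "Segments shorter than 10 ms" is read as
*retained* (good) runs being discarded, the natural reading once margins
fragment the record. The 45% rule counts every exclusion (threshold, margin,
short-segment). Residual comparison uses |residual|, catching deviations in
both directions. The Savitzky–Golay half-window (15 samples) at each end of
a test is flagged as an edge region and sits outside the 45% bookkeeping
entirely: the rule concerns saccade/artifact data loss, not filter edges.

## Learning metrics

Valid trial amplitudes are averaged within each testing block; gain =
amplitude / stimulus peak. ΔVOR is the percent change of block amplitude
relative to the pre-training baseline block; for OKR, the baseline is the
mean of blocks 1–3 and the post measure the mean of blocks 58–60, with
intermediate checkpoints at blocks 10–50 referenced to the same baseline
(single-block checkpoints by default; a window width is exposed because
block-averaged checkpoints are an equally defensible reading). Blocks with
no valid trial propagate as missing data — there is no imputation rule to
apply, and a zero would masquerade as a real null response. Percent changes
are computed on amplitudes; since gain shares the stimulus peak, gain-based
percent changes are identical (tested).

## Synthetic recordings

The generator inverts the measurement model: eye velocity
`offset + sign·g·A·sin(2πft + φ)` (sign: VOR opposes the head, OKR follows
the drum; φ = 0 is the ideal compensatory response) is integrated
analytically to position. Saccades are minimum-jerk position steps
(10τ³ − 15τ⁴ + 6τ⁵), parameterized by duration and signed peak velocity
(peak factor 15/8), placed by a Poisson process thinned to a 50 ms minimum
separation; every event is logged for ground-truth comparison. Sensor noise
is white Gaussian *velocity* noise (default interpretation of a °/s noise
figure) integrated into position, so the analysis chain sees noise of the
stated SD before its own filtering. Defaults mirror the study conditions:
1 kHz sampling (unstated in the protocols; chosen well above the 15 Hz band
so the 10/50 ms rules are integer sample counts), 45 s VOR tests × 3 per
block with 10 s gaps, baseline + one testing block per 10 min training
block, 60 × 50 s OKR blocks, saccade rate ~1/s with 40–200 °/s peaks,
2 °/s noise.

What the generator does **not** emulate: eye-plant biomechanics, torsion and
vertical components, sensor calibration error, slow drift, blinks, non-
stationary gain within a test, or saccade main-sequence structure. Passing
tests therefore demonstrate correctness of the analysis procedure under the
stated signal model, not robustness to every artifact class of real
recordings. Training-period traces are not synthesized by default since all
measurements are taken in the test periods.

## Statistics

Shapiro–Wilk (scipy) screens normality (n ≥ 3). The two-factor
repeated-measures design (genotype between animals × block time within) is
a mixed ANOVA, delegated to `pingouin.mixed_anova`; no sphericity correction
is applied by default (exposed as an option). Post-hoc pairwise comparisons
use Tukey's HSD (statsmodels) across all genotype × time cells, from which
named contrasts (between-group at a time point; within-group baseline vs
time point) are extracted. t-tests delegate to scipy, with the zero-variance
paired case mapped to (t = 0, p = 1). Calibration tests verify a ~5% type-I
rate for the interaction F under iid null simulations and > 95% power for a
35-point group effect (SD 10, n = 10/group) — both at 200 simulations.
Reported cell summaries are mean ± SEM strings that parse back to the
numbers displayed.

## Metaplasticity simulator

No quantitative model exists for the sliding-threshold hypothesis, so the
simulator is deliberately minimal and its outputs are ordinal. Each of
200 synapses (half task-relevant) has weight w ∈ [0, 1] (init 1) and LTD
threshold θ (baseline 1.0 arbitrary activity units; the enhanced-LTD
genotype divides baseline by 2). Poisson coactivation events (spontaneous:
0.2 /synapse/min at drive 0.7, hitting all synapses; training:
1 /synapse/min at drive 1.5, hitting task-relevant synapses) induce LTD
(w ← max(w − 0.2, 0)) only when drive > θ, and each induction slides θ up by
Δθ = 2. LTP-style episodes (VOR-decrease analogue) relax w toward 1 and θ
toward baseline exponentially (0.15 /min); activity suppression (diazepam
analogue) silences events while θ relaxes. θ never drops below baseline.
The parameter logic: spontaneous drive lies between the two genotype
baselines (aberrant induction only in enhanced-LTD); Δθ exceeds the training
drive so a single aberrant induction puts θ out of training's reach — the
plasticity-driven (not rate-driven) variant of the hypothesis; the
activity-driven alternative is a one-line change in `step`. The learning
readout is the mean training-period weight decrement over task-relevant
synapses normalized by the single-event decrement; its mapping to a
behavioural ΔVOR is affine with free scale and is never fitted to animal
data. With the defaults, 50-replicate means reproduce the target ordering
(naive enhanced-LTD ≈ 0; both rescues ≈ wild type; no wild-type boost from
pre-training; deficit returns when spontaneous activity resumes after
suppression).

## Problem sizes and numerical notes

Tests and the acceptance script use 45 s, 1 kHz single tests (100 for the
recovery study), 200-simulation statistical calibrations, and 50-replicate
simulator runs — sizes at which every Monte-Carlo margin in the suite is
comfortable while the whole suite runs in well under two minutes. The
sinusoid fit uses `numpy.linalg.lstsq`; the independent cross-check is a
Levenberg–Marquardt fit over (amplitude, phase, offset). Phase is reported
in (−180°, 180°]; amplitudes are non-negative by construction. Exclusion
bookkeeping is integer-sample arithmetic (margin = 50 samples, minimum
segment = 10 samples at 1 kHz), so fractions are exact rationals reproduced
exactly by an interval-arithmetic oracle on the same grid.

## Known limitations

- The Butterworth application mode and Savitzky–Golay order of the original
  analysis are not recoverable from the protocol description; both are
  configuration, with defaults chosen by the signal-fidelity arguments above.
- The trial-validity rule interacts with the first-pass fit: a single
  contiguous contamination of ~45% of a test biases the first fit enough
  that thresholding can miss it (distributed artifacts are handled well);
  this is a property of the specified procedure itself.
- The mixed ANOVA assumes compound symmetry when no sphericity correction is
  requested.
- The simulator makes qualitative predictions only; magnitudes of its
  readout are not comparable to behavioural percent changes without an
  (unfitted) affine map.
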
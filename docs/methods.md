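# Methods

Models, estimators, parameter defaults and numerical choices for
`shoalkin`. Companion to the API docstrings; everything stated here about
accuracy was computed by the test suite or the acceptance script
(`scripts/acceptance.py`).

## 1. Midline wave model and generator

A swimming fish's midline is modeled as a travelling lateral wave on an
inextensible body of unit length (all lengths in body lengths, BL):

```
y(s, t) = A(s) · sin(2π (f t − s / λ) + φ0)
A(s)    = a_head + (a_tail − a_head) · s^e
```

with arc-length coordinate `s ∈ [0, 1]` head→tail, tail-beat frequency `f`
(Hz), body wavelength `λ` (BL), and a monotone amplitude envelope `A(s)`
(exponent `e = 2` by default). The x-coordinates are reconstructed so that
consecutive midline points keep constant arc spacing
(`dx = sqrt(ds² − dy²)`): the generated polyline is inextensible, like a
digitized body axis, not a graph of `y(x)`. Gaussian digitization noise of
standard deviation `noise_sd_bl` is added independently per coordinate.

Realizability guard: the model is only a valid inextensible midline while
`max |∂y/∂s| < 1`. Parameter sets whose maximum slope reaches 0.995 raise
`ParameterError`. This is why the default tail amplitude is **0.08 BL**
rather than 0.10: at the shortest study wavelength (0.6 BL) a 0.10 BL tail
amplitude exceeds the slope bound.

Defaults (`WaveModelParams`): `f = 10 Hz`, `λ = 0.95 BL`,
`a_head = 0.02 BL`, `a_tail = 0.08 BL`, 200 midline points, 1000 fps,
36 mm body. These match a routine-swimming adult; the study generator
overrides them per stage (§6). Every generated dataset carries a
`SyntheticTruth` with the injected parameters and derived quantities
(envelope values at the measurement stations, analytic maximum curvature),
so estimators are always scored against exact ground truth.

## 2. Midline kinematics estimators

**Tail-beat cycles and TBF.** The oscillation signal is the mean lateral
excursion of the 5 tail-tip points, mean-subtracted. Zero crossings are
located by linear interpolation between samples; sign runs shorter than 3
samples are merged (hysteresis against noise-induced chatter). Two
boundary recovery rules make cycle *counts* faithful at record edges:
exact-zero boundary samples count as crossings, and a crossing lying up to
`max(1, 0.16·half-period)` frames beyond the record is reconstructed by
extrapolating one period from the last same-parity crossing (periods are
taken as `median` of second-differences of crossing times, which is immune
to the alternating offset a DC bias induces in consecutive half-periods).
TBF = (number of half-periods) / (2 × elapsed time); exact on noiseless
waves and median error 0.13% at 0.005 BL noise.

**Amplitudes.** Head/tail oscillation amplitude is the maximum deviation
of a single-harmonic (fundamental at the measured TBF) least-squares fit
to the 5-point head/tail mean signal over the detected cycles. Fitting the
fundamental rather than taking the raw max removes the upward
max-of-noise bias; on noiseless waves it is exact to the envelope truth.

**Curvature.** Local curvature is the inverse circumradius of three body
points, `κ = 4·area / (a·b·c)`, evaluated with a stencil spacing of 5% BL.
Maximum body curvature is the max over stations and frames of a cycle.
Chord-based circumcircle curvature *underestimates* the true continuous
curvature (one-sided error), verified ≤10% against the analytic envelope
maximum.

**Wave speed and wavelength.** The body wave is tracked in curvature
space, where the travelling phase is not masked by the envelope:

1. coordinates are smoothed along the body with a zero-phase
   Savitzky–Golay filter (window 31 points ≈ 15% BL, cubic; symmetric
   linear filters add no phase error, so noiseless estimates are
   unchanged);
2. signed three-point curvature profiles are computed per frame;
3. each body station's curvature time series is least-squares fit at the
   fundamental frequency, giving a per-station amplitude and phase ψ(s);
4. stations in the posterior half (`s ≥ 0.5`), where the envelope is
   strong, contribute; ψ is unwrapped, lightly smoothed, forced monotone;
5. per frame, crest positions are found by inverting
   `ψ(s) = π/2 + kπ − ω t` for each crest index `k`, and a common
   least-squares slope across crest trajectories gives the speed;
   wavelength = speed / TBF.

Guards: a straight body (curvature amplitude < 0.1/BL after scaling) or a
flat phase profile yields `NaN` with a warning rather than a number.
Accuracy: noiseless 3×3 (f, λ) grid worst-case error 3.9% (a second-order
phase-offset drift from the envelope gradient, largest at λ = 1.3);
median errors 1.4–1.5% at 0.005 BL noise.

## 3. Shoal cohesion metrics

**Mean separation distance.** Mean over frames of the mean over fish of
each fish's mean distance to the others, divided by the mean body length.
For equal-weight shoals this equals the unordered-pair average; five
collinear fish at unit spacing give exactly 2.0 BL.

**Position switch rate.** Streamwise (flow-axis) projections are resampled
to a common 10 Hz grid; for each fish pair the sign of the projected gap
is passed through a Schmitt trigger with a ±0.05 BL dead band, and each
confirmed sign flip counts as one switch. The rate is total switches per
second. The hysteresis band makes the count monotone non-increasing in
band width and immune to sub-band jitter; noiseless simulated trajectories
return exactly the realized switch count (minus at most the final
unobservable step), and across 200 jittered simulations the mean estimate
is within 3 standard errors of the injected Poisson rate.

## 4. Respirometry

Oxygen traces are closed-chamber concentration series (mg O₂ L⁻¹) sampled
every 60 s with phase labels `rest`, `recovery`, `reset`.

**Resting MO₂** is the magnitude of the OLS slope over the final 30 min of
the rest phase (the early acclimation transient is excluded). Rising
traces clamp to 0 with a warning.

**Peak recovery MO₂** slides a 3-min window (4 samples at 60-s sampling)
across the recovery phase and takes the largest OLS decline rate.
`reset` samples split the phase into runs and never enter a window. The
last rest-labeled sample is prepended to the first recovery run: it is the
chamber state at recovery onset, and the drop from it to the first
recovery sample is recovery consumption; without it the steepest first
minute is unobservable. Because the post-exercise rate decays
monotonically, any finite window averages it down — the estimator bounds
the true peak from below (one-sided bias). For the reference trace
(rest 0.8, peak 2.5, τ = 15 min) the noiseless estimate is 2.341, matching
the continuous first-window mean
`rest + (peak − rest)(τ/W)(1 − e^{−W/τ}) = 2.3408`. A 3-min window was
chosen over 10 min because the 10-min mean of the same trace (2.04) no
longer resolves the early-recovery peak at all; with noise the max over
windows acquires a small upward counter-bias, which shortening the window
further would amplify.

**Q₁₀** = `(K₂/K₁)^(10/(T₂−T₁))`. A rate doubling over 28→32 °C gives
`2^2.5 = 5.65685…`. Properties: swapping the rates inverts Q₁₀; swapping
(rate, temperature) pairs jointly relabels the conditions and leaves Q₁₀
unchanged; rescaling both rates changes nothing. `stage_q10_table`
averages per-shoal rates within each stage × temperature cell and prefers
recorded mean temperatures over nominal treatments when available; empty
cells yield NaN with a warning.

Rates are deliberately not mass-adjusted: temperature contrasts are made
within a stage, where chamber and animals are identical, so mass scaling
cancels in every Q₁₀.

## 5. Permutation ANOVA

F statistics come from sequential (Type I) sums of squares via
Gram–Schmidt orthogonalization of the term blocks (intercept, A, B, A:B);
with balanced cells this equals Type III. p-values are by permutation:

- **one-way**: raw labels are permuted. When the number of distinct label
  arrangements is ≤ 20,000 they are enumerated exhaustively and the
  p-value is exact (identity arrangement included, so p ≥ 1/N); otherwise
  Monte Carlo with `p = (exceedances + 1)/(m + 1)`.
- **two-way**: each term uses the Freedman–Lane scheme — residuals of the
  reduced model excluding the tested term are permuted, added back to the
  reduced fit, and the term's F is recomputed (vectorized over
  permutations).

Terms left with zero estimable degrees of freedom (e.g. the interaction
when a design cell is empty) report NaN. Calibration: type-I error at
α = 0.05 is 0.059 (one-way) and 0.054 (Freedman–Lane interaction) over
1,000 null datasets at m = 499 (acceptance seed 1), within [0.03, 0.07].
Benjamini–Hochberg adjusted p-values are emitted alongside the per-test
flags in `within_speed_sweep`; NaN p-values are excluded from the
adjustment rather than propagated.

## 6. Synthetic study design

`default_study_design()` emulates a 3-stage × 2-temperature (28/32 °C)
design with 10 replicate shoals of 5 fish per stage (odd shoal numbers →
32 °C; juvenile shoal 9 absent), swimming at stage-specific flow speeds,
plus one oxygen trace per shoal. Injected per-stage truths:

| stage    | BL (mm) | TBF @1.5 BL/s | λ (BL) | head amp | sep (BL) | rest rate | peak rate | rest Q₁₀ | peak Q₁₀ |
|----------|--------|----------------|--------|----------|----------|-----------|-----------|----------|----------|
| larva    | 8.2    | 22 Hz          | 0.60   | 0.04     | 3.0      | 0.6       | 1.5       | 1.96     | 1.03     |
| juvenile | 13.9   | 14 Hz          | 0.75   | 0.03     | 1.8      | 0.8       | 2.4       | 9.98     | 1.37     |
| adult    | 36.4   | 7 Hz           | 0.95   | 0.02     | 1.0      | 1.0       | 2.5       | 2.19     | 2.53     |

TBF rises 1 Hz per BL/s of flow speed and by a stage-specific factor at
the warm treatment; thermal rate ratios over the 4 °C interval are
`Q₁₀^0.4`. Realism knobs: 0.003 BL midline noise at 250 fps, 4% CV
between shoals, 0.3 Hz TBF spread between fish within a shoal, 0.01 BL
trajectory jitter at 25 Hz, 0.01 mg/L oxygen sensor noise, recorded tank
temperatures jittered 0.2 °C around nominal. `zero_effect_design()` keeps
the layout but flattens every injected effect, for null calibration.

### Generator realism limits

- Midlines are strictly periodic single-harmonic waves: no turns, glides,
  burst-and-coast, or amplitude drift within a recording.
- Shoal trajectories are station-holding with Poisson station exchanges;
  there is no hydrodynamic interaction, leadership structure, or lateral
  dynamics beyond jitter.
- Oxygen traces are piecewise-deterministic (linear rest, exponential
  recovery decay) with white noise; real probes drift and chambers mix
  imperfectly.
- Noise is Gaussian and independent per sample; real tracking errors are
  temporally correlated and heavy-tailed.

Consequently, estimator accuracies quoted here are upper bounds on
real-data performance, and with sensor noise the max-over-windows peak
MO₂ estimator inflates weak thermal contrasts (e.g. the juvenile peak Q₁₀
reads ≈2.1 in the noisy study against an injected 1.37, while resting
Q₁₀s recover closely).

## 7. Numerical choices

- All slope fits are plain OLS on time in hours; no robust weighting
  (windows are short and outliers are a generator non-feature).
- Curvature stencil 5% BL: wide enough that 0.003–0.005 BL point noise
  does not dominate the second difference, narrow enough that the
  one-sided chord underestimate stays within 10%.
- Savitzky–Golay window 31 points (or the largest odd number ≤ n−1),
  polyorder 3, `mode="interp"`.
- Permutation p-values use `(count + 1)/(m + 1)` (Monte Carlo) so they are
  valid (never zero); exhaustive enumeration returns the exact proportion.
- Seeds: every stochastic component takes an explicit seed; study
  sub-seeds derive from `numpy.random.SeedSequence(entropy, spawn_key)`
  reduced mod 2³¹−1.

## 8. Limitations

- The wave estimator needs a visible curvature crest in the posterior
  half; near-rigid or very long-wavelength swimmers (λ ≫ 1.3 BL untested)
  return NaN or degrade.
- Cycle-boundary extrapolation assumes ≥2 interior crossings; recordings
  shorter than one full cycle are rejected rather than guessed.
- The switch-rate Schmitt trigger undercounts exchanges completed within
  one 10 Hz resample step at very high switch rates.
- Sequential SS is order-dependent for unbalanced designs; the fixed
  A → B → A:B order is documented, not configurable.
- Peak MO₂ is a lower bound by construction; comparisons across
  laboratories must match the window length.
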
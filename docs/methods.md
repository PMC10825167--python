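# Methods

## The measurement model

A disc alternates between a fixed colour/luminance `L_f` and a variable
one `L_v` every half-period `h` (default 0.283 s, i.e. 34 frames at
120 Hz), giving a tagging frequency `f = 1/(2h)` ≈ 1.77 Hz.  The pupil's
luminance pathway responds to the *perceived* luminance step between the
two phases, so the stimulus-locked pupil trace carries three read-outs:

* a sustained baseline offset proportional to the mean perceived
  luminance relative to the background;
* an oscillation at `f` whose amplitude grows with the magnitude of the
  perceived difference |g·L_v − L_f| (where `g` is the observer's
  relative gain for the variable colour);
* a phase reversal of that oscillation of ~180° between conditions where
  the variable colour is perceptually darker vs lighter than the fixed
  one.

At perceptual equiluminance (`g·L_v = L_f`) the differential drive
vanishes, so the tagged amplitude is minimal and the phase transitions
through its inversion.  The estimate of interest is the luminance
`L_min` at the amplitude minimum and the ratio `R = L_f / L_min`, which
equals `g` for the generative observer.

Assumptions: the pupil behaves as a time-invariant low-pass system over a
trial, noise is additive and independent of the stimulus, and the
perceived luminance of the variable colour scales linearly with its
photometric luminance over the tested range.

## Analysis pipeline

1. **Calibration (optional).**  Tracker arbitrary units map to
   millimetres as `d = θ·√units` with `θ = d_ref/√units_ref` from an
   artificial-pupil recording (8 mm target by default).  The √ reflects
   area-mode tracking.  The minimum location is scale-invariant, so the
   pipeline is routinely run on raw units.
2. **Smoothing.**  30 ms Gaussian; the kernel is truncated at ±half the
   window and renormalised (σ = window/5, so the window holds ±2.5σ).
   At 1.77 Hz the pass-band attenuation is negligible (< 10⁻³); the
   smoothing exists to tame tracker jitter in the plotted traces.
3. **Baseline correction**, per trial, either the pre-stimulus mean over
   (−0.1, +0.1) s around disc onset or the mean over the subsequent FFT
   window (default; slightly better signal-to-noise since it zeroes the
   DC bin exactly).
4. **Averaging** across the repeats of each condition (pointwise mean ±
   SEM, SD/√n).  Grids must match exactly; no resampling is performed.
5. **Integer-cycle FFT.**  The window spans exactly ρ tagging periods,
   `t2 = t1 + ρ·(2h)`, so the tagging frequency falls on DFT bin ρ and
   rectangular windowing causes no leakage at that bin.  Amplitudes are
   single-sided (`2|X_k|/N`; `|X_0|/N` at DC), phases in degrees, cosine
   convention referenced to the window start, wrapped to (−180°, 180°].
   Samples are taken from the half-open interval [t1, t2), which keeps
   `N = ρ·2h·rate` exact on a uniform grid.
6. **Tuning-curve fit.**  A cubic smoothing spline over (level,
   amplitude), smoothing parameter chosen by generalised
   cross-validation; the minimum is located by dense grid search (2001
   points by default, ≥ 1000 enforced) restricted to the tested range —
   no extrapolation.  Minima on the range edge are flagged
   ``boundary`` (the session should be re-centred, the ratio is not
   trustworthy).
7. **Phase confirmation.**  Phases are unwrapped over sorted levels; the
   two plateaus are medians over the first/last quartile of levels; a
   transition requires a plateau-to-plateau excursion ≥ 90°.  The
   transition midpoint (linear interpolation of the crossing of the
   plateau mean) confirms the spline minimum when it falls within one
   luminance step (configurable).  ``combined_luminance`` is the
   unweighted mean of the two estimates; no variance weighting is
   attempted.

### Window placement

`default_t1` starts the window on the first colour-reversal boundary at
or after 1 s post-onset — past the pupil's onset transient, and on a
boundary so that phase is referenced to the stimulus cycle.  With 3.5 s
trials this leaves ρ = 4 cycles.  For the simulation recovery studies we
instead use the maximal window the trial affords — ρ = 5 cycles starting
at the second reversal boundary (0.566 s): the cycle-count trade-off is
part of the method (fewer cycles = noisier amplitudes but an unchanged
minimum), and on the noiseless control the earlier start leaves the
recovered ratio unchanged to < 10⁻³ while the longer window reduces the
amplitude noise by ~30%.

## Companion psychometric estimators

Minimum motion yields per-level 2AFC direction counts, modelled with the
Quick (Weibull-family) function

    p(x) = γ + (1 − γ − λ)(1 − 2^(−(x/α)^β)),

fitted by binomial maximum likelihood over (log α, log β) with
multi-start (log-spaced α grid × β ∈ {1, 2, 4, 8}, Nelder–Mead).  For a
direction task coded as proportion-rightward, γ = λ = 0, and the point
of subjective equality (the 50% crossing) equals α in closed form.
Fitted slopes ≥ 64 flag perfectly separable (step-like) data, where the
slope is unidentifiable; all-0 or all-1 response sets are rejected
outright.  Whether β should be free or fixed is not settled; it defaults
to free with multi-start.

Minimum flicker is a matching task: each repeat records the variable
luminance at minimum perceived flicker, summarised as mean ± SD of
`fixed/match`.

## Method comparison

Pearson r (and Spearman ρ as the Pearson correlation of midranks) with
Fisher z = arctanh(r) as effect size and a one-tailed p from
`t = r√(n−2)/√(1−r²)` on n−2 df; Bland–Altman differences are taken
second − first, limits mean ± 1.96·SD (n−1 denominator), CIs
`t₀.₉₇₅,ₙ₋₁·SD/√n` for the mean and `t₀.₉₇₅,ₙ₋₁·SD·√(3/n)` for each
limit.

## The synthetic observer

No pupil recordings ship with the package; `pftm.simulate` generates
them.  The perceived drive is a square wave between `L_f` and `g·L_v`
against a background at `L_f`; its mean and alternating components are
scaled separately (`k_dc = 0.01`, `k_osc = 0.02` mm per cd/m²) and passed
through a gamma-density impulse response (shape 8, scale set so the
kernel peaks at 0.45 s) with a 0.15 s transport delay, so the visible
onset lag lands in the 0.5–0.7 s range typical of pupil responses.
Brighter perceived stimuli constrict (negative sign).  Measurement noise
is AR(1) Gaussian, stationary SD 0.02 mm, lag-one correlation 0.97 at
1 kHz — strongly red, like real pupil noise; at 1.77 Hz it carries ~58×
the power density of equal-variance white noise, which is what makes the
recovery studies noise-limited rather than trivially easy.  Baseline is
5 mm.  Per-trial noise seeds are spawned deterministically from the
master seed (`numpy.random.SeedSequence`), so sessions reproduce
sample-for-sample across runs and platforms.

The generator reproduces the features the analysis exploits — onset
latency, baseline offset, tagged oscillation with amplitude proportional
to the perceived difference, a clean 180° phase reversal, red noise.  It
does **not** emulate blinks/saccade artefacts (gap flags and
interpolation are exercised with hand-made masks instead), pupillary
unrest/hippus beyond AR(1), melanopsin-driven slow dynamics, attention
or arousal effects, nonlinear perceived-luminance compression, or gaze
geometry.  Passing recovery tests therefore show the pipeline is correct
and statistically efficient under the stated noise model, not that the
defaults are tuned to any particular eye-tracker.

Study conditions used by the recovery tests and the acceptance script:
same-colour control with fixed 11.04 cd/m² and 21 levels over
1.6–33.05 cd/m² × 10 repeats; a gain-0.85 observer with fixed
21.04 cd/m² and 15 levels over 4.2–37.9 cd/m² × 10 repeats; the
cycle-trade-off comparison with fixed 20.34 cd/m², 15 levels × 10
repeats in 4.2 s trials (long enough to hold five cycles from the
default window start); 20 seeds per study, medians reported.  2AFC
recovery uses α = 22, β = 4, 9 levels × 50 trials.

## Numerical choices and degenerate inputs

* Window endpoints are computed in exact decimal arithmetic on the
  shortest float representations, so `0.3 + 4×0.567 = 2.568` exactly;
  binary addition would be 1 ulp off and integer-cycle bookkeeping is
  clearer when printed times agree with hand arithmetic.
* Uniform-grid tolerance 1 ns; rate vs spacing tolerance 10⁻⁶; condition
  labels are floats matched at 10⁻⁹.
* Requested FFT frequencies must land on a bin within 10⁻⁶ cycles.
* Non-finite samples must be flagged as gaps; gaps ≤ 200 ms are linearly
  interpolated, longer gaps (or gaps touching the trace edge) reject the
  trial.  Off by default for synthetic data, which generates none.
* Downsampling requires an integer decimation factor and uses a
  zero-phase FIR anti-alias filter with linear-trend padding (constants
  and slow drifts pass through the boundaries unchanged).
* Degenerate psychometric data (all-same responses) and all-zero
  amplitude curves raise instead of returning arbitrary numbers.

## Known limitations

* The amplitude minimum is located on the smoothing spline; for strongly
  asymmetric level placement the GCV spline can bias the minimum by a
  fraction of a level step.  The raw arg-min condition is reported
  alongside as a cross-check.
* Phase-transition detection assumes a single inversion; sessions whose
  range does not straddle equiluminance return "no transition" and the
  estimate is flagged unconfirmed/boundary rather than extrapolated.
* The second harmonic of the tagged response and time-resolved
  (wavelet) analyses are out of scope.
* Eye-tracker native formats are not parsed; input is the documented
  CSV dialect (one sample per row).
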
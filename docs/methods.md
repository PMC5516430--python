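# Methods

## Data model

A record is a 24-h list of NN intervals (normal-to-normal heartbeat
intervals, ms) with beat times in seconds from record start, an 8-ms
quantization step (125-Hz Holter sampling), and a sleep/wake partition from
a diary.  Cleaning excludes beats outside 300–2000 ms (artifacts) or
differing by more than 20% from the previous accepted beat (ectopy); these
thresholds are standard Holter practice for healthy adults and are
configurable.  Excluded beats are removed, never interpolated — the
resampler bridges the gaps — and a record losing more than 20% of its beats
is refused unless forced.  Diary boundaries can optionally be refined within
±30 min to the largest sustained shift of the 15-min running median NN
(sleep lengthens NN); the diary always wins when refinement is off.

## Spectral estimation

Two evenly sampled tachograms are derived per record:

* **short stream**, 2 Hz by cubic-spline interpolation (Nyquist 1 Hz), cut
  into consecutive 5-min windows for HF/LF/VLF band powers;
* **long stream**, 0.1 Hz by 10-s bin means of the 2-Hz spline, cut into
  180-min windows stepped by 5 min for ULF power and the power-law slope.
  Bin averaging acts as a crude anti-alias filter whose response has nulls
  at multiples of 0.1 Hz, so LF/HF power does not fold into the slow stream.

Each window is fitted with an autoregressive model by the Burg (maximum
entropy) recursion, which guarantees a stationary model and a strictly
positive density S(f) = 2σ²Δt / |1 − Σ aₖ e^(−i2πfkΔt)|², one-sided, in
ms²/Hz, integrating to the window variance.

**Order policy.**  Short windows (n = 600) use AIC over orders 1–30 — the
band structure there is a few narrow oscillations, which AIC captures well.
Long windows (n = 1080) use a fixed order of 30 after the window mean is
removed.  This choice was calibrated on synthetic 1/f^β series with known
exponent: AIC chooses orders near 6 on power-law spectra and flattens the
fitted slope by ~0.15, and a within-window linear detrend biases the slope a
further ~0.07 toward zero, while the fixed-order, mean-removed fit recovers
generating exponents between −1.2 and −0.9 with |bias| ≲ 0.03.  Both the
criterion and the detrend mode remain configuration options.

**Band powers** are trapezoidal integrals of the model density on a
log-spaced grid (100 points/decade) refined around every AR pole: a pole
near the unit circle is a near-Lorentzian peak whose half-width,
−ln|r|/(2πΔt), can be far narrower than any fixed grid step, and without
refinement a narrow oscillation's power is silently missed.  ULF band-3
(0.001–0.005 Hz) deliberately extends past the ULF total's upper edge
(0.003 Hz) and into VLF territory, following the band conventions of
long-term HRV work; bands are integrated independently.

**Power-law slope.**  β is the OLS slope of log₁₀ S against log₁₀ f over
10⁻⁴–10⁻² Hz on the same per-decade grid (equal weight per decade); the
scaling exponent is α = (β + 1)/2.  β is invariant under any positive
rescaling of the spectrum.  Window values are averaged over the 24-h, awake
and asleep spans, a window belonging to the span of its midpoint — the rule
that yields ~70 asleep windows of ~250 for a 6.17-h sleep.  Δβ is the asleep
minus awake mean (positive: the spectrum is flatter during sleep).  Because
"Δα" is ambiguous — (Δβ+1)/2 under the published convention versus Δβ/2 as
the algebraic difference of span α means — both are emitted under explicit
names (`delta_alpha_of_delta_beta`, `delta_alpha_halved`).

## Cosinor rhythmometry

The per-record β window series (midpoint times, hours after arising) is
fitted by least squares with y = M + βc·cos(ωt) + βs·sin(ωt), ω = 2π/24 h,
giving MESOR M, amplitude A = √(βc²+βs²) and acrophase
φ = −atan2(βs, βc) in (−360°, 0].  Within-record serial correlation of the
overlapping windows is ignored for the single-record standard errors, as in
classical cosinor practice; group-level inference is unaffected because it
uses only the between-subject scatter.  The population-mean cosinor averages
the per-subject (βc, βs) vectors (sessions of a condition are averaged per
subject first); the zero-amplitude test is Hotelling's T² on the mean
vector, F = (k−2)/(2(k−1))·T² with (2, k−2) degrees of freedom, whose 95%
confidence ellipse excludes the origin exactly when p < 0.05.  Group
parameter comparisons: paired t on MESORs and amplitudes, paired Hotelling
T² on the rhythm vectors (joint amplitude/acrophase), and a paired t on
wrapped acrophase differences as the separate phase test.

## Group statistics

Earth is the per-subject mean of the Pre and Post sessions; space the mean
of the three in-flight sessions — the convention that exactly reproduces the
published group means and t statistics from the bundled per-astronaut table.
The space-vs-Earth contrast is a two-sided one-sample t on per-subject
log₁₀(space/Earth) ratios (defined whenever the pair shares a sign, which a
guard enforces; for β both values are negative and the ratio is positive).
The in-flight comparison is a plain between-groups one-way ANOVA, F with
(g−1, N−g) degrees of freedom — the computation that reproduces the
published F values; a subject-blocked repeated-measures variant is provided
under its own name.  Bonferroni adjustment defaults to m = 5, the five
indices tested side by side (β, ULF, VLF, LF, HF), which reproduces the
published adjusted p of 0.060 for ULF.  Note: in the bundled reference
table's β row the ANOVA column value 0.403 equals the *p-value* of
F = 0.955; the statistics table therefore reports F and p in separate
columns.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with every true
parameter recorded in a ledger:

* **Exponent profile** β(t) = MESOR + A·cos(2π(t−t_wake)/24h + φ) +
  step·1[asleep], phase zero at arising.  Defaults: Earth MESOR −1.163,
  space −0.949 (shift +0.214), acrophase −308° (Earth) / −317° (space),
  target asleep−awake contrast Δβ = 0.43; the step is solved in closed form
  so the realized contrast matches Δβ after the cosine's own contribution.
  The circadian amplitude of β is not a published quantity; its default 0.15
  is a free parameter chosen so the zero-amplitude test is clearly
  significant at k = 7 while β stays in a physiological range.
* **Colored background** by Fourier synthesis over the whole record: one set
  of random spectral phases shared across a grid of candidate exponents
  (step 0.1), pointwise interpolation between the coherent realizations
  giving the time-varying exponent.  Per-segment synthesis was rejected: a
  30-min segment carries no power below 5.6·10⁻⁴ Hz — inside the fit range —
  and flattens fitted slopes to ≈ −0.65 for a −1.2 target.  The spectrum is
  normalized so the ULF-band power is 3000 ms² at every exponent (the
  published ULF values are of order 10³–10⁴ ms²) and tapered as f⁻⁴ above a
  0.04-Hz knee so background power beyond the ~1-Hz beat-sampling Nyquist
  does not alias into LF/HF through beat generation.
* **Oscillations** as narrow-band Gaussian processes at 0.10 Hz (LF, 650 ms²)
  and 0.25 Hz (HF, 120 ms²); **beats** by integrate-and-fire from the
  tachogram, times quantized to 8 ms; **sleep** onset ~23:30 ± 30 min with
  duration 6.17 ± 1.38 h per record; **ectopics** at 3/h as premature beats
  with compensatory pauses, labelled normal so the cleaning stage must find
  them.  Per-subject Earth MESORs are drawn N(−1.163, 0.10); the space MESOR
  adds the shift exactly, so the injected contrast is known per subject.
  Everything is deterministic under a fixed seed.

What the generator does *not* emulate: respiratory and baroreflex coupling,
nonstationary arousals, movement artifacts with realistic morphology,
multifractality, or any dependence of band powers on the exponent.  Passing
recovery tests therefore demonstrates the estimator chain is calibrated for
power-law Gaussian inputs with the study's window geometry — not that it is
robust to every feature of real Holter data.

## Validation geometry and problem sizes

Recovery checks mirror how windows arise in practice: 180-min windows are
cut from full 24-h synthetic streams (windows synthesized in isolation lack
the sub-window frequencies a real window inherits from its record and fit
~0.06 shallow).  The slope check uses 50 windows from ten independent
streams; the end-to-end check uses the full 7-subject × 5-session cohort on
the slow stream; the zero-amplitude type-I rate uses 1000 null cohorts of 7
subjects × 50 samples.  A 24-h record yields 288 five-min windows and 253
sliding 180-min windows exactly; real records lose a second or two to beat
alignment at the edges and may count one fewer.

## Numerical notes and limitations

* The Burg recursion stops early if the prediction-error energy vanishes
  (noise-free deterministic inputs); the model at the highest reachable
  order is returned.
* Identically-zero paired differences in parameter tests are reported as
  t = 0, p = 1 ("no evidence") rather than NaN; a degenerate between-subject
  scatter in the population cosinor yields a zero-area ellipse with p = 0
  for a non-zero mean vector.
* Fmax is reported as a statistic without a p-value (its reference
  distribution is tabulated); Bartlett's test carries the p.
* The 2-Hz spline tachogram near the HF band edge is limited by the ~1-Hz
  mean beat rate; HF estimates from records with slow heart rates are
  attenuated.  Amplitude estimates of the β rhythm absorb part of the sleep
  step's fundamental, so fitted amplitudes exceed the injected cosine
  amplitude by design.
* Single-record cosinor confidence intervals ignore window overlap and are
  anti-conservative; use the population-level inference for conclusions.
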
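# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and the design decisions taken
where the problem was genuinely open.

## Signals and preprocessing

**Inertial speed.** The 6-channel IMU trace (accelerometer and gyroscope,
arbitrary units, 200 Hz) is reduced to a scalar speed: the mean across
channels of the absolute first difference. The derivative leaves n − 1
samples; the sample at index t represents the interval [t, t + 1], and any
series aligned to it is truncated to the common length. Speed is unitless
(no IMU calibration is attempted) and invariant to constant channel offsets.

**Condition windows.** Sessions contain two injections. Analysis windows are
fixed offsets from them: baseline BL = [−25, −5] min before the first
injection; V and K = [+5, +25] min after a vehicle or ketamine injection;
LD = [+65, +85] min after L-DOPA (equivalently [+5, +25] after the control
vehicle given at +60); LD→K = [+5, +25] after a ketamine that follows
L-DOPA. An early-LD window [+35, +55] is exposed for spectral summaries.
All offsets are configurable; a baseline that would start before the session
is clipped at 0 with a warning rather than an error. The compact timeline
used by the cohort pipeline's smoke and calibration runs keeps the same
structure with 4–5 min windows.

**Binning and smoothing.** Spike counts use left-closed right-open bins
tiling the window, so total count is conserved. The moving average is
centred with shrinking edge windows (an O(n) cumulative-sum implementation),
which maps a constant input to itself exactly.

**LFP.** Analyses assume 500 Hz input; a raw trace is decimated with an
8th-order zero-phase anti-alias filter (integer factors only).

## Spectral analysis

Spectrograms are Hann-tapered 1 s frames with 0.5 s hop, zero-padded to
0.5 Hz bin spacing and restricted to 1–120 Hz (exactly 239 bins; a 20 min
window yields 2399 frames). Per-frequency z-scoring uses the mean/SD across
the frames of the analysis window; zero-variance rows become z = 0 with a
log entry.

IRASA separates the aperiodic component: for each resampling factor h in
1.1…1.9 (step 0.05, the original method's default set) the signal is
resampled by h and 1/h (polyphase, exact rationals), Welch PSDs (4 s Hann
segments, 50% overlap) are taken on the unchanged frequency axis, and their
geometric mean cancels the fractal self-similarity scaling while displacing
oscillatory peaks; the median across the h-set is the fractal spectrum and
the residual (total − fractal) the oscillatory one. The residual may be
negative; it is kept in the container (with the negative fraction flagged)
and floored at zero only inside band-power summaries. Band defaults:
beta 15–30 Hz, wide gamma 35–120 Hz, finely tuned gamma (FTG) 75–85 Hz
around the ~80 Hz dyskinesia rhythm, ketamine gamma 45–55 Hz. "FTG power"
is a band mean, not a single bin; the width is configurable.

Estimator note: the oscillatory residual of a pure 1/f² input is zero-mean
noise whose per-bin SD shrinks as (segments per window × realizations)^−1/2.
The residual check in the acceptance suite uses 600 s windows averaged over
20 realizations, at which the worst-case bin is below 5% of the fractal.

## Coupling analyses

**Coupling spectrum.** Speed is averaged within each spectrogram frame
(arithmetic mean over the frame's 200 Hz samples — the frames overlap, so
adjacent frames share half their speed samples) and correlated with each
frequency row (Pearson, two-sided t-test p, df = n − 2). Constant speed in
a window makes all correlations undefined; the result is flagged rather
than raised. No multiple-testing correction is applied per spectrum by
default; Holm-adjusted p-values are available on the results object.

**Band regression.** OLS with every 0.5 Hz z-scored power bin in the band
as a predictor (171 predictors for 35–120 Hz) and frame-averaged speed as
the outcome; reported as adjusted R². Collinear predictors are dropped via
pivoted QR with a log entry.

**Unit-timescale coupling.** Counts in 5 ms bins (one speed sample per bin
at 200 Hz), smoothed at 18 window sizes (50–4000 ms); the smoothed rate is
correlated with the *unsmoothed* speed. Units silent in the window are
flagged and excluded from aggregates. The per-unit scalar summary is the
unweighted mean R² over the 18 windows; the per-animal grain averages that
over units.

## Unit characterisation

Waveform features come from the largest-amplitude channel: trough = global
minimum, peak = maximum after the trough (monophasic waveforms raise an
error that flags the unit); half-widths are measured at 50% of each
extremum with linear interpolation. Classification is two-stage k-means
(25 restarts, fixed seed): stage 1 on standardized (peak-to-trough ratio,
half-width ratio) with the narrow cluster labelled putative interneurons;
stage 2 splits the wide cluster on standardized (log autocorrelogram peak
lag, log rate). The low-rate cluster is labelled LFWW — the classes are
named by firing rate, so the rate ordering decides, and the lag ordering is
logged as a corroborating diagnostic (in generated data bursty LFWW cells
have *short* ACG peak lags, so lag alone would be ambiguous).

Inclusion requires a clean refractory period — the maximum autocorrelogram
rate at lags ≤ 2 ms must stay below the mean rate over the remaining lags
(a numeric operationalisation of "no early ACG peak") — and a rate above
0.1 Hz in at least one analysis window.

The LvR statistic uses the standard signs
[1 − 4·IᵢIᵢ₊₁/(Iᵢ+Iᵢ₊₁)²][1 + 4R/(Iᵢ+Iᵢ₊₁)]; only these reproduce the
anchors 0 (tonic), 1 (Poisson), >1 (bursty) that define the measure. The
refractoriness constant R defaults to 0 (plain Lv), with a 5 ms option; R
and the ISIs share units (seconds internally). Lv at R = 0 is invariant to
time-rescaling; LvR with R > 0 deliberately is not.

## Ensemble analysis

Pair correlations are Pearson correlations of binned spike counts (1 s
default, 100 ms alternative) over all unordered pairs of included units;
pairs with a silent unit are flagged missing. State similarity is the
Pearson correlation between two states' pair-correlation vectors, matched
on shared pairs — near 1 means the between-neuron structure is preserved,
near 0 that it has reconfigured. Pair-correlation change keeps pairs
significant (p ≤ α, uncorrected) in *either* state — so correlations that
appear and ones that disappear both count — and reports the signed ΔR
distribution (Wilcoxon signed-rank for a median shift) and |ΔR|. Raw R
values are compared without Fisher-z, matching the procedure the analyses
replicate; a Fisher-z sensitivity option would be a two-line extension.

A finite-size caveat discovered during development: if a second state's
factor loadings are *exactly* orthogonal to the first's, the expected
similarity is not 0 but ≈ −k/n (k factors, n units), because
tr(G·H) = 0 for the two Gram matrices forces the off-diagonal products to
sum to minus the diagonal ones. With the default k = 2 and n = 30 the
planted "reconfigured" truth is −0.07, which is what the recovery tests
expect under |similarity| < 0.1.

## Synthetic sessions

The generator's defaults define the study conditions the tests exercise.

* **Movement**: rectified Ornstein–Uhlenbeck latent speed (τ = 2 s) with
  per-condition mean/SD in arbitrary units — BL 0.8/0.4, V 1.0/0.5,
  K 1.6/0.8, LD 2.6/1.2, LD→K 2.6/1.4 — movement low at baseline, raised by
  ketamine, highest during dyskinesia. The 6 IMU channels are random walks
  whose Gaussian increments have scale s(t)·√(π/2), so the folded mean of
  each increment equals the latent speed and `compute_inertial_speed`
  recovers it unbiasedly.
* **LFP**: 1/f^χ background (χ = 2, spectrally shaped Gaussian noise,
  50 µV RMS) plus condition-gated narrowband oscillators — bandpass noise
  carriers with amplitude envelope max(0, a + b·s(t)). The lesioned
  hemisphere plants anti-coupled beta (22 Hz, b < 0) at BL/V,
  movement-coupled broadband gamma at BL/V/K, coupled ~50 Hz gamma under
  ketamine, and a high-power *zero-gain* 80 Hz rhythm under L-DOPA — power
  without movement coupling, the dyskinesia-gamma phenotype. Control
  hemispheres receive only the movement gamma and ketamine gamma.
* **Spike trains**: λ(t) = softplus(base + gain·s(t) + factor drive),
  sampled by time-rescaled gamma renewal so rate coupling and ISI
  regularity are set independently, with a 2 ms dead time enforced.
  Classes: IN (narrow waveform, 12 Hz, shape 2), LFWW (wide, 1.5 Hz,
  shape 0.4 → LV ≈ 3/(2k+1) > 1, bursty), HFWW (wide, 8 Hz, shape 1,
  near-Poisson). Rate↔speed gains are positive in BL/V/K, zero under LD
  (the planted unit-level decoupling) and halved under LD→K (partial
  restoration). Waveforms are biphasic Gaussian-lobe templates with 5%
  per-unit feature jitter over 4 tetrode channels.
* **Pair structure**: unit-variance OU latent factors (τ = 1 s) enter the
  softplus argument through per-condition loading matrices. The default
  drive SD is 2.5 Hz, chosen so 1 s count correlations land at ~0.1–0.2 —
  the range typical of cortical count correlations; an earlier 0.5 Hz
  default produced ~0.01, indistinguishable from the null, and was
  rejected because the structure must be *plantable* to be recoverable.
  "Reconfiguration" conditions (ketamine states) use loadings orthogonal to
  baseline with matched column norms, changing the correlation pattern
  without changing its magnitude.

One RNG stream per session is keyed by the seed, with spawned child streams
per component (movement, IMU, LFP, spikes) so components are independently
reproducible. Sessions are bit-identical under a fixed seed.

**What the generator does not emulate**: spike-sorting noise and electrode
drift, 60 Hz line noise and artefacts, striatal signals, non-stationarity
within a condition, inter-animal variability beyond the seed, and any
biophysical network mechanism. Passing recovery tests therefore shows the
*analyses* are correct and sensitive at realistic effect sizes — not that
real recordings will show these effects.

## Statistics harness

The a-priori sample size uses the one-sample (paired) noncentral-t
construction: power(n) = P(|T| > t₁₋α/2,df | ncp = d√n), d = |Δµ|/σ, the
smallest n meeting the target returned; a vectorised Monte-Carlo simulation
(10⁵ tests) is the independent check. A two-sample variant is exposed.
Group comparisons in the cohort report use standard scipy routines
(Kruskal–Wallis by default for the non-normal per-unit measures) with
Bonferroni–Holm adjustment (own step-down implementation, cross-checked
against statsmodels in the tests).

## Problem sizes

The default test and acceptance runs use: 20 min single-condition sessions
for coupling recovery (2399 frames); a 30/50/100-unit population for cell
typing; 100 null units for the timescale null distribution; 40-min
two-state sessions with 30 units for ensemble recovery; 20 × 600 s
realizations for the IRASA residual check; compact-timeline cohorts
(4–5 min windows) for end-to-end pipeline and null-cohort calibration.

## Known limitations

* The coupling spectrum treats frames as independent when computing
  p-values; overlapping frames and slow speed autocorrelation make the
  effective df smaller, so per-bin p-values are anticonservative (the
  planted-recovery tests rely on R magnitudes, not p).
* Band regression with 171 predictors on ~2400 frames overfits modestly;
  adjusted R² corrects the first order of this but model-selection
  uncertainty is not propagated.
* The refractory inclusion contrast is a heuristic; heavily bursty units
  with true short-latency ACG mass near 2 ms could be penalised.
* The LD→K condition plants a reduced-but-nonzero broadband gamma gain, so
  FTG-band coupling is not zero there (only LD is fully decoupled), which
  matches the partial-restoration phenomenology but means FTG-band
  quantities in LD→K sit between LD and V.
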
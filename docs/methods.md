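# Methods

This note documents the models, conventions and numerical choices behind
`ecaptools`, in the order a recording flows through the pipeline.

## Units and conventions

Voltages are microvolts in memory; disk bundles store µV with the unit
declared in the JSON sidecar (files declaring volts are converted on
read).  Time is seconds from recording start; epoch and window time bases
are milliseconds post-stimulus.  All intervals — epochs, fiber windows,
spike-count epochs — are half-open `[start, end)`.  Fiber windows and the
detrending fit windows are in ms.

## Synthetic recordings

The simulator emulates the statistical structure of large-animal nerve
recording sessions (multi-fascicle nerves instrumented with cuff, LIFE and
microneurography electrodes downstream of a bipolar stimulation cuff,
sampled at 25 kHz), not their biophysics: there is no volume-conductor or
axon-model computation, and electrode gains are knobs, not derived
quantities.

**Neural layer.** Each stimulation pulse inserts, per channel and fiber
class, a biphasic template (negative lobe leading, as for a passing
depolarization dipole; zero mean; duration defaulting to 20/velocity ms so
faster fibers give briefer deflections) at latency distance/velocity,
scaled by the channel gain and by the recruitment fraction — a scaled
logistic sat/(1 + e^(−k(I−I50))) in stimulation current, with an exact
zero at 0 mA because no stimulus recruits nothing (a raw logistic would
leave a small fictitious response in 0 mA control trains).  Sensory
sessions insert a triphasic Ricker-wavelet spike (1.5 ms, dominant
positive peak, ±30% amplitude jitter) at homogeneous-Poisson times per
epoch; the same spike train reaches every channel, scaled by an
electrode-kind gain (microneurography 1.0, LIFE 0.08, cuff 0.04 by
default) so microelectrodes see multi-unit activity that macroelectrodes
bury in noise.

**Artifact layer (common mode).** Per-pulse exponential decay
A·e^(−b(t+c)) shared across channels up to a per-channel scale factor;
ventilator bumps at 15/min and cardiac bumps at 90/min
(derivative-of-Gaussian wavelets, 300 ms and 50 ms); tremor as Poisson
bursts of enveloped 10 Hz oscillation.

**Noise layer.** White noise whose RMS is the quadrature sum of the global
and per-channel settings; a 60 Hz mains tone with random phase; drift as a
sum of 20 random tones below 10 Hz calibrated to the requested RMS.

**Randomness.** A single root seed feeds per-(layer, channel, trial) child
streams (`SeedSequence` spawn keys).  Consequences used by the tests:
identical configs are bit-reproducible; adding a layer does not perturb
the others; and the sum of separately simulated layers equals the combined
simulation exactly (the renderer adds neural + common-mode + noise in that
fixed order, so the float sums agree bit for bit).

**Referencing model.** Local-tissue referencing returns neural signal plus
the common-mode layer at full amplitude.  Bipolar returns the neural
component at the contact minus at a contact one spacing further from the
stimulation site; tripolar subtracts the mean of the two flanking
contacts.  Both cancel the common-mode layer exactly and keep the
channel's own uncorrelated noise — an idealization of real common-mode
rejection.

**Default scenario parameters** (presets): electrode distances 0.05 / 0.08
/ 0.11 m; filtered-band white-noise floors 2.53 µVrms (cuff, LIFE) and
3.51 µVrms (microneurography); ECAP gains 1.0 / 0.34 / 0.21 for cuff /
LIFE / microneurography (plausible ratios for macro- vs micro-electrode
summation, configurable); Aβ fiber at 50 m/s with 20 µV template peak and
recruitment midpoint 1 mA, slope 4/mA; B fiber at 10 m/s, 4 µV, midpoint
3 mA.  Stimulation trains default to 25 Hz, 200 µs pulses.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: electrode-tissue coupling and impedance drift,
fiber-population latency dispersion (optional broadening is off by
default), EMG spillover, correlated inter-channel noise, amplifier
nonlinearities, and any biology behind the gain ratios.

## Filtering

Both paths use forward-backward (zero net group delay) application of a
1st-order Butterworth high-pass at 100 Hz and a Gaussian-impulse-response
FIR low-pass at 3 kHz.  "Corner" of the Gaussian stage is defined as its
single-pass −3 dB point — the same convention as the Butterworth corner —
giving σ_t = √(ln 2)/(2π f_c), truncated at ±4σ and normalized to unit DC
gain.  A Gaussian's step response is monotone, so the low-pass cannot ring
after the stimulation-artifact impulse and an overshoot cannot masquerade
as an evoked deflection.  The asynchronous path adds a Hamming-window FIR
band-stop around 60 Hz.  With 2001 taps at 25 kHz a Hamming FIR's
transition band (~41 Hz) is far wider than a 4 Hz notch, leaving 60 Hz
nearly untouched; the defaults are therefore a 55–65 Hz stop band with
8001 taps (single-pass |H(60)| ≈ 0.009), both configurable.  Edge handling
is odd-symmetric extension of length 3× the longest single-pass support;
shorter recordings are rejected rather than silently producing edge
garbage.

## ECAP quantification

Median (not mean) averaging across a train's pulses: the point-wise median
of n Gaussian sweeps has RMS σ√(π/(2n)) — ~25% less efficient than the
mean at equal n, but robust to artifact-laden sweeps.  The √n averaging
law is used for the uncorrelated-noise budget, consistent with the
worked numbers in the noise analysis.

The 20% velocity tolerance is operationalized as follows: a window edge is
"truncating" the ECAP when |trace| exceeds 3× the quiescent noise RMS
(estimated from samples after, else before, the window) within 3 samples
of that edge; the corresponding velocity bound is then relaxed in 1%
increments up to 20%.  Window equalization sets the common duration to the
largest of the channels' minimal deflection-containing sub-windows
(deflection support = samples with |v| > 3× noise RMS), so no channel
loses signal while distant channels stop integrating extra noise;
signal-free channels center the common duration in their velocity window,
and when every channel is signal-free the smallest input window sets the
duration.

Exponential detrending fits y = A·e^(−b(x+c)) by least squares on samples
inside 2.2–2.4 ms and 5.8–6.0 ms (defaults tied to the emulated geometry;
configurable), initialized log-linearly when the segment is
positive-going.  The model is over-parameterized (A and c trade off
through A·e^(−bc)); only the fitted curve matters, so this is harmless.
By default subtraction happens only when the fitted decay at the first fit
window exceeds 3× the noise RMS of the quiescent last 10% of the epoch —
artifact contamination is the exception — with an always-on mode
available.

Velocity authenticity uses the depolarization trough (minimum voltage) as
the latency landmark on each channel — one consistent polarity landmark,
because the extremum of |v| hops between the lobes of a biphasic
deflection under noise — and fits distance against latency by least
squares.  Zero latency spread marks a common-mode artifact: velocity is
reported non-finite and the trace non-authentic.

## Dose-response

Curves are normalized at 5 mA (nearest tested dose if absent, recorded);
normalization is a pure y-rescaling, so ECp currents are invariant to it.
The logistic fit initializes at y0 = min(y), L = range, x0 = half-range
crossing, k = 4/span, with two jittered restarts before declaring
non-convergence; L and k are constrained positive and y0 ≥ 0.  A curve
whose range is below 5% of its maximum is reported flat and unconverged —
this feeds the non-functional-channel screen.  Rescaling fitted curves to
[0, 1] is presentation only; it never precedes fitting.

## Spike detection

Threshold = baseline mean + 6 SD (baseline 1–6 s; the mean term absorbs
offsets).  The threshold applies to the positive-going signal — matching
the literal rule — with an absolute-value mode behind a flag; the
simulator's spike template is dominant-positive accordingly.  At 6σ the
per-sample false-crossing probability on Gaussian noise is ~1×10⁻⁹, i.e.
~2×10⁻³ expected detections per 90 s session at 25 kHz.  Supra-threshold
onsets within a 1 ms refractory/merge period collapse into one event
(whether study "spikes" were crossings or bursts is unknowable from the
protocol; the merge rule is our declared convention).  Baseline
spontaneous activity inflates the threshold slightly; no robust-SD
correction is applied, by design.

## Noise budget and statistics

Thermal noise √(4·k_B·T·R·Δf) with defaults T = 300 K and Δf = 2900 Hz
(the 100 Hz–3 kHz analysis band): only real impedance generates thermal
noise, so applying it to a mostly capacitive 1 MΩ microelectrode gives an
upper bound (6.9 µVrms), not the true electrode noise.
Non-functional-channel screening flags a channel whose noise or mains RMS
exceeds 3× the same-electrode-type median ("high" is undefined in the
emulated protocol; 3× is the configured default) or whose dose-response is
flat; single-channel types are skipped with a notice.  Evoked heart-rate
change is the deviation of largest absolute value from the 1–3 s pre-stim
baseline mean, returned signed (bradycardia negative).

Cohort comparisons take replicate means per subject and electrode type,
normalize to the reference type within subject, log10-transform, check
normality by Shapiro–Wilk (a rejection attaches a warning, it does not
block the test), and run a one-sided one-sample t-test of the log ratios
against 0 — the equivalent formulation of a one-sided comparison of two
electrode types normalized within subject; a paired two-sample variant is
available.  µ, SE and the 95% t-distribution CI are reported on the ratio
scale.  Zero-variance inputs produce explicitly degenerate results, never
silent NaNs.  The sequential gate passes α down the pre-registered outcome
order until the first p ≥ α, which fails and demotes everything after it
to exploratory.  The EC10 repeated-measures ANOVA short-circuits a table
with no within-subject type variation to F = 0, p = 1.

## Verification problem sizes

The simulation-based calibrations run at sizes chosen to keep deskside
reruns fast while leaving their conclusions unchanged: EC10 recovery uses
150-pulse (6 s) trains on one cuff channel, 16 doses over 0–10 mA, median
over 50 seeds (median-averaged noise at 150 sweeps, ~0.26 µVrms, is
already far below the simulated ECAP, so 750-pulse trains would only
shrink an error comfortably inside the 15% band); spike calibration uses
the full 100 × 90 s noise-only sessions plus 800 injected spikes; the
median-averaging check uses the full n = 750; the cohort type-I
calibration uses 1000 simulated cohorts of 6 subjects.

## Known limitations

Single-exponential detrending cannot represent multi-phase artifact decays;
the equalization heuristic assumes one contiguous deflection per window;
the sequential gate implements fixed-order gatekeeping only (no graphical
alpha-recycling); and simulator-calibrated performance numbers transfer to
real recordings only to the extent the noise and artifact layers above
resemble them.
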
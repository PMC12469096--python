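# Methods

## The detection model

`pamrange` estimates how far from a fixed hydrophone a broadband pulsed
call can be detected by an automated detector, and with what probability.
The model is the passive sonar equation applied independently in contiguous
300 Hz frequency bands. A call is detectable in band f at range R when its
received band level exceeds the ambient band level by at least the
detection threshold DT:

    SL(f) − TL(f, z, R) ≥ NL(f) + DT

where TL is the transmission loss for a caller at depth z. TL is
represented by a log-range law fitted to samples exported from any external
propagation model; the fitted form is stored as PL(f,z,R) = A(f,z) −
n(f,z)·log10 R with the sign convention that PL is the level *change*
applied to SL (so A is the intercept at R = 1 m, near zero or negative for
physical loss, and n > 0 is the geometric spreading coefficient — 10 for
cylindrical, 20 for spherical spreading). Solving for the range at equality
gives the closed form

    R(f) = 10^((A(f,z) + SL(f) − NL(f) − DT) / n(f,z))

which is strictly increasing in A and SL and decreasing in NL and DT, and
obeys an exact decade property: ±n dB of noise multiplies or divides R by
10. The call's maximum detection range for one noise minute is the maximum
of R(f) over bands (ties broken toward the lowest band); the band achieving
it is tracked to build the argmax-band histogram.

Because NL is a per-minute time series, one caller configuration yields a
detection-probability curve: P(r) = fraction of minutes whose maximum
detection range is at least r — an empirical survival function, by
construction non-increasing in r and confined to [0, 1].

## Monte Carlo structure

Two sources of caller variability are propagated:

* **Broadband source level** — Gaussian draws (defaults: 155.1 ± 6.5 dB re
  1 µPa·m for Southern Resident killer whale pulsed calls; 145.3 ± 6.8 for
  Northern Residents). Each draw is distributed across bands along a fixed
  spectral slope (−0.66 dB per band SRKW, −0.27 NRKW, fitted by OLS to
  high-SNR call spectra). The per-band levels are affine in the band index
  and normalized so their *power sum* equals the drawn broadband level
  exactly (to 1e-9 dB); this is the only allocation that keeps the drawn
  broadband value physically meaningful. An `anchor_first` mode (first band
  pinned at the broadband value) exists for sensitivity work.

* **Caller depth** — a log-logistic (Fisk) distribution on depth with
  location μ = 2.0212 on the log scale and scale σ = 0.7739, fitted to
  resident killer whale Dtag data truncated at 200 m (stations sit in water
  shallower than that). Sampling uses quantile-range rescaling: p uniform
  on (0, F(z_max)), then the closed-form quantile — exact truncation at
  deterministic cost. A uniform-depth alternative supports sensitivity
  swaps. One depth applies to all minutes of a realization: the depth is a
  property of the hypothetical caller, not of time.

The default run crosses a pool of 100 source-level draws with a pool of
100 depths, giving 10,000 realizations, each producing one probability
curve over all minutes. (A flag switches to 10,000 independent
(SL, depth) pairs instead of the cross product.) The ensemble is
summarized by pointwise 25/50/75 percentile envelopes, the argmax-band
histogram, and median detection ranges at probability marks 0.1/0.5/0.9.

The engine evaluates R(f) in closed form per (realization, minute, band) —
log10(range) throughout, so no overflow at large ranges — and touches the
range grid only to sample curves and invert them. The test suite contains a
deliberately naive 4-deep loop over (realization, minute, band, grid range)
that checks the detection inequality through the fitted PL table directly;
the two routes agree to 1e-9 on random small instances.

### Median-range inversion

The range at probability p is the largest grid range where the selected
curve is still ≥ p, refined by linear interpolation in log10(range) between
the bracketing grid points. A curve starting below p reports 0 m; a curve
that never falls below p within the grid reports the grid maximum with an
explicit `unbounded` flag (never a silent grid max). The headline median
inverts the 50th-percentile envelope; a `per_realization` mode inverts
every realization curve and takes the median of the ranges — both are
available, and the run manifest records which was used, since the two can
differ when the ensemble is skewed.

## Inputs and fitted components

**Band scheme.** Contiguous equal-width tiling; membership is half-open
[low, high) except the final band, closed at the top edge, so energy is
never double-counted. The killer whale default (1000–14800 Hz / 300 Hz)
has 46 bands; 300 Hz is the minimum bandwidth the target automated
detector accepts.

**Ambient band levels.** From CSV, or computed from calibrated
single-channel audio: pressure via a flat hydrophone sensitivity (dB re
1 V/µPa) plus gain, then per averaging window (default 60 s; shorter
windows change little and the window is a config knob) a Welch PSD (1 s
Hann segments, 50% overlap) integrated across band edges. The 1-minute
band SPL is thus the mean-square pressure over the full window — the
averaging convention is stated here because vendor tools differ. Digital
silence raises an error by default (a flag substitutes a −120 dB floor)
so −inf never propagates silently. Broadband level is the power sum
10·log10 Σ 10^(SPL_i/10). Noise stratification cuts minutes at the 33rd
and 66th percentiles of the broadband series (low < lower threshold,
high > upper, ties to medium), giving equal terciles to within one minute
for continuous data.

**Propagation-loss fits.** Ordinary least squares of PL on log10(range)
per (band, source-depth bin) cell; depth bins default to 0–200 m in 10 m
steps. All transects are pooled by default (one (A, n) per cell is what
the detection formula consumes); per-transect fits aggregated by median
coefficients are available, and with a single transect the two are
identical. Cells with fewer than two distinct ranges, n ≤ 0, or r² below a
configurable floor (default 0.5) are flagged unusable — excluded from the
argmax with a one-time warning listing the bands, never silently kept.
Coefficients at an arbitrary depth come from linear interpolation across
usable bin centers, clamped beyond the fitted span. Receiver depth is
implicit in the supplied samples (bottom-mounted hydrophone) and never
modeled.

**Depth-model MLE.** Nelder-Mead on (μ, log σ) of the untruncated
log-logistic likelihood applied to samples ≤ z_max (samples above the
truncation depth are discarded first, mirroring a fit to tag depths below
station water depth); non-convergence raises with the optimizer status.
Starting values come from the median and quartile spread of log-depth.

## Sensitivity and stratified runs

All randomness flows from a single seed through named substreams (one per
pool), so re-running with one factor swapped — source-level spectrum,
noise series, propagation table, or depth distribution — shares the exact
SL and depth draws with the base run. A swap replaced by itself therefore
yields a difference of exactly 0, and each swap may change exactly one
factor (two-factor swaps are rejected). Stratified runs share pools across
strata the same way, so between-stratum differences isolate the noise
effect.

## Synthetic scenarios

The generators emulate the statistical structure the model assumes, not
ocean physics:

* **Ambient noise**: a base spectrum declining with frequency (ambient
  sound is loudest at the low end of the band span), a shared AR(1)
  temporal term, independent per-band jitter, and transient broadband
  "vessel passage" bumps (1-minute rise, ~5-minute exponential decay) at a
  Poisson rate. No Wenz curves or wind regressions — the events exist to
  make stratification meaningful, nothing more.
* **PL samples**: generated from linear-in-(band, depth) truth rules for A
  and n, as the mean of three jittered sub-band evaluations (matching how
  a propagation-model supplier averages within-band frequencies), with the
  jitter scaled so the averaged residual SD equals the requested value
  exactly.
* **Presets**: `toy3band` (3 bands, 60 minutes — small enough for
  exhaustive brute-force oracles), `quiet_inshore` and `noisy_strait`
  (46 bands, 240 minutes, differing by ~15 dB of base noise). All use the
  resident-killer-whale source-level and depth defaults; the noise and PL
  numbers are fixture design chosen once for realistic kilometre-scale
  detection ranges, not measurements. Every scenario ships a truth record
  sufficient to regenerate it bit-identically from (preset, seed).

Passing tests on these scenarios demonstrate the correctness of the
machinery — closed forms, fits, seeding, monotonicity — under the model's
own assumptions. They do not validate the assumptions against real
soundscapes: real noise has diurnal/seasonal structure, flow noise, and
recorder self-noise; real propagation departs from a single log law (ducts,
multipath); call directionality and noise-dependent source-level
adjustment (Lombard response) are deliberately out of scope, which is why
results are framed as *on-axis* detection probabilities.

## Numerical choices and limitations

* Range grid: log-spaced, 10 m – 100 km, 200 points (site medians of
  interest span roughly 0.1–40 km); inversion interpolates in log-range.
* All curve arithmetic in float64; probabilities are exact multiples of
  1/n_minutes; percentile envelopes use linear-interpolation percentiles.
* Detection-range comparison is inclusive (Rmax ≥ r counts as detected at
  r), matching the survival-function definition.
* Problem sizes in the shipped tests and the acceptance script (toy
  scenario, 240-minute 46-band site, 100 small oracle instances, 50–100
  fit-recovery seeds) were chosen so the complete check runs in about a
  minute on one core while still exercising every code path at full
  default realization counts.
* The fitted (A, n) table treats transect pooling, depth binning, and the
  r² floor as configuration; there is no wave-equation or ray-tracing
  solver, no geoacoustics, no sound-speed profiles, no call detector
  model beyond the scalar DT, and no multi-animal or density estimation
  layer.
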
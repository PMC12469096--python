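# pamrange

Monte Carlo detection-range modeling for broadband cetacean calls recorded
at fixed passive acoustic monitoring (PAM) stations.

A network of bottom-mounted hydrophones can only report whale presence out
to the distance at which a call still stands above the ambient noise. That
distance is not a constant: it moves minute by minute with the soundscape,
varies with the caller's depth and source level, and differs across
frequency because both the call energy and the noise are frequency
dependent. `pamrange` estimates the **probability of on-axis detection as a
function of range** for pulsed calls (developed for Southern and Northern
Resident Killer Whales, applicable to any broadband caller), propagating
all of that variability through a seeded Monte Carlo simulation.

## Model

Work band by band on a contiguous tiling of the call's frequency span
(default 46 bands of 300 Hz between 1000 and 14800 Hz). With band source
level SL(f) (dB re 1 µPa·m), ambient noise level NL(f) (dB re 1 µPa),
detection threshold DT (dB, default 5), and a log-range propagation-loss
law fitted per band and source depth z,

    PL(f, z, R) = A(f, z) − n(f, z) · log10 R ,

the per-band detection range is the closed form

    R(f) = 10 ^ ( (A(f,z) + SL(f) − NL(f) − DT) / n(f,z) ) ,

and a call's maximum detection range is Rmax = max over bands of R(f).
For one hypothetical caller (one broadband source-level draw, tilted across
bands by the population's spectral slope with total power conserved, and
one depth drawn from a truncated log-logistic model), evaluating Rmax
against every recorded noise minute gives one detection-probability curve
P(r) = fraction of minutes with Rmax ≥ r. Crossing 100 source-level draws
with 100 depth draws yields an ensemble of 10,000 curves, summarized by
25/50/75 percentile envelopes, median detection ranges at P = 0.1/0.5/0.9,
and the per-band share of argmax outcomes.

Everything upstream of the simulation is also provided: per-minute band SPL
from calibrated WAV audio (Welch PSD integrated over band edges), broadband
power sums and tercile noise stratification, OLS fitting of (A, n) from any
external propagation model's output, maximum-likelihood fitting of the
log-logistic depth model, spectral-slope fitting from high-SNR call
spectra, and synthetic generators for every input so the full pipeline runs
without field data.

## Worked example

```sh
pamrange generate --preset toy3band --seed 7 --out scenario/
pamrange simulate --config scenario/config.yaml --out run/
```

The second command prints

```
median detection range (P=0.5): 6368 m
```

meaning: on this synthetic 3-band site, for the median (50th-percentile)
curve of the 10,000-realization ensemble, a calling whale has a 50% chance
of on-axis detection out to about 6.4 km. `run/` contains
`ensemble_summary.csv` (range vs p25/p50/p75 detection probability),
`median_ranges.csv` (ranges at P = 0.1/0.5/0.9 for each percentile curve,
with an explicit flag for curves that never fall below the mark inside the
range grid), `argmax_band_histogram.csv` (which band set Rmax, per band),
and `manifest.json` (config echo, seed, input digests — identical config
and seed reproduce every CSV byte for byte).

The same library calls, in Python:

```python
import numpy as np
from pamrange import (DetectionConfig, fit_pl_loglaw, gen_site_scenario,
                      median_range_at_probability, run_monte_carlo)

sc = gen_site_scenario("toy3band", seed=7)
pl = fit_pl_loglaw(sc.pl_samples, sc.scheme, depth_bins=np.arange(0, 201, 40))
ens = run_monte_carlo(sc.noise, pl, sc.sl_spec, sc.depth_params,
                      DetectionConfig(seed=7))
print(ens.n_realizations)                        # 10000
print(median_range_at_probability(ens, 0.5))     # (6368.2, False)
```

Other subcommands: `stratify` re-runs the simulation separately for
low/medium/high noise terciles (shared seed, so differences isolate the
noise effect), `sensitivity` swaps one factor at a time (source-level
slope, noise series, propagation table, depth distribution) and reports
median-range differences, and `fit-pl` / `fit-depth` / `fit-slope` /
`bandlevels` expose the individual fitting stages.

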
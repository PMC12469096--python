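"""Synthetic scenario generators.

Every input the detection-range pipeline consumes can be generated here with
the statistical structure the model assumes, so the whole pipeline is
testable without field recordings or external propagation-model output:

* ambient band-level matrices with a frequency-decreasing base spectrum, a
  shared AR(1) temporal term, independent band jitter, and transient
  broadband "vessel passage" bumps (a fixture design, not a physical ocean
  noise model);
* propagation-loss sample tables following ``A - n*log10(R)`` plus Gaussian
  residuals, mimicking the supplier's averaging of three sub-band
  evaluations;
* sloped call band spectra for slope-fit testing;
* log-logistic caller depths via :mod:`pamrange.depth`.

Each generator is deterministic under its RNG and every scenario ships a
``truth`` record sufficient to regenerate it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import AmbientSeries, BandScheme, make_band_scheme, write_ambient_csv
from .depth import DepthModelParams
from .propagation import PLSampleTable, write_pl_samples_csv
from .source_level import SourceLevelSpec

__all__ = [
    "SiteScenario",
    "gen_ambient_series",
    "gen_pl_samples",
    "gen_call_band_spectrum",
    "gen_site_scenario",
    "write_scenario",
    "PRESETS",
]


def gen_ambient_series(
    scheme: BandScheme,
    n_minutes: int,
    base_level_at_f_low: float,
    spectral_decay: float,
    temporal_sd: float,
    ar1_coeff: float,
    event_rate_per_hour: float,
    event_gain_db: float,
    rng: np.random.Generator,
    band_jitter_sd: float = 0.0,
    site_label: str = "synthetic",
    season_label: str = "",
) -> AmbientSeries:
    """Synthetic minutes x bands ambient SPL matrix.

    Per-minute band level = (base_level - spectral_decay * band_index)
    + shared AR(1) temporal term (stationary SD ``temporal_sd``,
    lag-1 coefficient ``ar1_coeff``) + independent N(0, band_jitter_sd)
    band jitter + broadband vessel-passage bumps arriving at a Poisson rate
    (1-minute linear rise, 5-minute exponential decay, peak
    ``event_gain_db``).  With ``temporal_sd = band_jitter_sd = 0`` and no
    events every minute equals the base spectrum.
    """
    if n_minutes < 1:
        raise ValueError("need at least one minute")
    if not (0.0 <= ar1_coeff < 1.0):
        raise ValueError("AR(1) coefficient must lie in [0, 1)")

    base = base_level_at_f_low - spectral_decay * np.arange(scheme.n_bands)

    # shared temporal term: stationary AR(1) with SD temporal_sd
    temporal = np.zeros(n_minutes)
    if temporal_sd > 0:
        innov_sd = temporal_sd * np.sqrt(1.0 - ar1_coeff**2)
        temporal[0] = temporal_sd * rng.standard_normal()
        eps = innov_sd * rng.standard_normal(n_minutes)
        for t in range(1, n_minutes):
            temporal[t] = ar1_coeff * temporal[t - 1] + eps[t]
    else:
        rng.standard_normal(n_minutes + 1)  # keep stream layout stable

    jitter = (
        band_jitter_sd * rng.standard_normal((n_minutes, scheme.n_bands))
        if band_jitter_sd > 0
        else 0.0
    )

    bump = np.zeros(n_minutes)
    if event_rate_per_hour > 0:
        n_events = rng.poisson(event_rate_per_hour * n_minutes / 60.0)
        starts = rng.integers(0, n_minutes, size=n_events)
        t = np.arange(n_minutes, dtype=float)
        for s in starts:
            dt = t - s
            profile = np.where(
                dt < 0, 0.0, np.where(dt < 1.0, dt, np.exp(-(dt - 1.0) / 5.0))
            )
            bump = np.maximum(bump, event_gain_db * profile)

    spl = base[None, :] + temporal[:, None] + jitter + bump[:, None]
    timestamps = np.array([f"m{t:06d}" for t in range(n_minutes)])
    return AmbientSeries(
        timestamps=timestamps,
        spl=spl,
        scheme=scheme,
        site_label=site_label,
        season_label=season_label,
    )


def gen_pl_samples(
    scheme: BandScheme,
    depth_grid,
    A_of,
    n_of,
    ranges,
    residual_sd: float,
    rng: np.random.Generator,
    n_transects: int = 1,
) -> PLSampleTable:
    """Propagation-loss samples from a known log law.

    ``A_of(band_index, depth)`` and ``n_of(band_index, depth)`` define the
    truth; each sample is the mean of three jittered evaluations of
    ``A - n*log10(R)`` (emulating a supplier averaging three in-band
    frequencies), with the jitter scaled so the averaged residual SD equals
    ``residual_sd`` exactly.  ``residual_sd = 0`` gives noiseless samples.
    """
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges <= 0):
        raise ValueError("ranges must be positive")
    depth_grid = np.asarray(depth_grid, dtype=float)

    rows = []
    for tr in range(n_transects):
        for z in depth_grid:
            for b in range(scheme.n_bands):
                A = float(A_of(b, z))
                n = float(n_of(b, z))
                clean = A - n * np.log10(ranges)
                if residual_sd > 0:
                    sub = clean[None, :] + residual_sd * np.sqrt(3.0) * rng.standard_normal(
                        (3, ranges.size)
                    )
                    pl = sub.mean(axis=0)
                else:
                    pl = clean
                for r, v in zip(ranges, pl):
                    rows.append((r, z, b, v, f"t{tr}"))
    df = pd.DataFrame(
        rows, columns=["range_m", "source_depth_m", "band_index", "pl_db", "transect_id"]
    )
    return PLSampleTable(data=df, scheme=scheme)


def gen_call_band_spectrum(
    scheme: BandScheme,
    slope: float,
    top_level: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Affine call band spectrum ``top_level + slope * band_index`` plus jitter."""
    idx = np.arange(scheme.n_bands, dtype=float)
    levels = top_level + slope * idx
    if noise_sd > 0:
        levels = levels + noise_sd * rng.standard_normal(scheme.n_bands)
    return levels


@dataclass
class SiteScenario:
    """A fully self-consistent synthetic monitoring-site scenario."""

    scheme: BandScheme
    noise: AmbientSeries
    pl_samples: PLSampleTable
    sl_spec: SourceLevelSpec
    depth_params: DepthModelParams
    truth: dict
    seed: int


def _linear_rule(c0: float, c_band: float, c_depth: float):
    def rule(band: int, depth: float) -> float:
        return c0 + c_band * band + c_depth * depth

    return rule


# Preset generating parameters.  Source-level and depth constants are the
# resident killer whale defaults; the noise/PL numbers are fixture design
# (documented in docs/methods.md), not measurements.
PRESETS: dict[str, dict] = {
    "toy3band": {
        "scheme": (1000.0, 1900.0, 300.0),
        "n_minutes": 60,
        "noise": dict(
            base_level_at_f_low=80.0, spectral_decay=1.0, temporal_sd=2.0,
            ar1_coeff=0.6, event_rate_per_hour=1.0, event_gain_db=10.0,
            band_jitter_sd=0.5,
        ),
        "pl": dict(
            A=(-8.0, -0.5, 0.02), n=(15.0, 0.5, 0.0),
            depths=(10.0, 50.0, 100.0, 150.0, 190.0),
            ranges=("log", 1.0, 4.3, 25), residual_sd=0.5, n_transects=1,
        ),
        "source_level": dict(mean_db=155.1, sd_db=6.5, slope_db_per_band=-0.66, label="SRKW"),
        "depth_model": dict(mu=2.0212, sigma=0.7739, z_max_m=200.0),
        "pl_fit": dict(depth_bin_width_m=40.0, r2_floor=0.5, pooling="pooled"),
    },
    "quiet_inshore": {
        "scheme": (1000.0, 14800.0, 300.0),
        "n_minutes": 240,
        "noise": dict(
            base_level_at_f_low=78.0, spectral_decay=0.35, temporal_sd=2.5,
            ar1_coeff=0.85, event_rate_per_hour=0.5, event_gain_db=8.0,
            band_jitter_sd=0.8,
        ),
        "pl": dict(
            A=(-6.0, -0.08, 0.02), n=(16.0, 0.02, -0.004),
            depths=tuple(np.arange(5.0, 200.0, 10.0)),
            ranges=("log", 1.0, 4.7, 40), residual_sd=0.8, n_transects=1,
        ),
        "source_level": dict(mean_db=155.1, sd_db=6.5, slope_db_per_band=-0.66, label="SRKW"),
        "depth_model": dict(mu=2.0212, sigma=0.7739, z_max_m=200.0),
        "pl_fit": dict(depth_bin_width_m=10.0, r2_floor=0.5, pooling="pooled"),
    },
    "noisy_strait": {
        "scheme": (1000.0, 14800.0, 300.0),
        "n_minutes": 240,
        "noise": dict(
            base_level_at_f_low=93.0, spectral_decay=0.30, temporal_sd=3.0,
            ar1_coeff=0.8, event_rate_per_hour=2.0, event_gain_db=12.0,
            band_jitter_sd=1.0,
        ),
        "pl": dict(
            A=(-8.0, -0.10, 0.015), n=(17.0, 0.02, -0.003),
            depths=tuple(np.arange(5.0, 200.0, 10.0)),
            ranges=("log", 1.0, 4.7, 40), residual_sd=0.8, n_transects=1,
        ),
        "source_level": dict(mean_db=155.1, sd_db=6.5, slope_db_per_band=-0.66, label="SRKW"),
        "depth_model": dict(mu=2.0212, sigma=0.7739, z_max_m=200.0),
        "pl_fit": dict(depth_bin_width_m=10.0, r2_floor=0.5, pooling="pooled"),
    },
}


def gen_site_scenario(preset: str, seed: int) -> SiteScenario:
    """Generate a complete scenario from a named preset, deterministic under seed.

    ``toy3band`` is small enough for exhaustive brute-force oracles;
    ``quiet_inshore`` and ``noisy_strait`` use the full 46-band scheme and
    differ by their base noise levels.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    scheme = make_band_scheme(*p["scheme"])
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_pl = (np.random.default_rng(c) for c in ss.spawn(2))

    noise = gen_ambient_series(
        scheme, p["n_minutes"], rng=rng_noise, site_label=preset, **p["noise"]
    )

    plp = p["pl"]
    kind, lo, hi, npts = plp["ranges"]
    assert kind == "log"
    ranges = np.logspace(lo, hi, npts)
    pl_samples = gen_pl_samples(
        scheme,
        depth_grid=np.asarray(plp["depths"]),
        A_of=_linear_rule(*plp["A"]),
        n_of=_linear_rule(*plp["n"]),
        ranges=ranges,
        residual_sd=plp["residual_sd"],
        rng=rng_pl,
        n_transects=plp["n_transects"],
    )

    slp = p["source_level"]
    sl_spec = SourceLevelSpec(
        mean_bb=slp["mean_db"], sd_bb=slp["sd_db"],
        slope=slp["slope_db_per_band"], label=slp["label"],
    )
    dmp = p["depth_model"]
    depth_params = DepthModelParams(mu=dmp["mu"], sigma=dmp["sigma"], z_max=dmp["z_max_m"])

    truth = {"preset": preset, "seed": seed, **{k: v for k, v in p.items()}}
    truth["pl"] = {**plp, "depths": list(plp["depths"])}
    truth["scheme"] = list(p["scheme"])
    return SiteScenario(
        scheme=scheme,
        noise=noise,
        pl_samples=pl_samples,
        sl_spec=sl_spec,
        depth_params=depth_params,
        truth=truth,
        seed=seed,
    )


def write_scenario(scenario: SiteScenario, outdir) -> dict:
    """Write a scenario directory: ambient CSV, PL CSV, run config YAML, truth JSON."""
    import json

    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ambient_path = outdir / "ambient.csv"
    pl_path = outdir / "pl_samples.csv"
    write_ambient_csv(scenario.noise, ambient_path)
    write_pl_samples_csv(scenario.pl_samples, pl_path)

    config = {
        "site": {"label": scenario.noise.site_label, "season": scenario.noise.season_label},
        "inputs": {"ambient_csv": "ambient.csv", "pl_samples_csv": "pl_samples.csv"},
        "band_scheme": {
            "f_low_hz": scenario.scheme.f_low,
            "f_high_hz": scenario.scheme.f_high,
            "width_hz": scenario.scheme.width,
        },
        "source_level": {
            "mean_db": scenario.sl_spec.mean_bb,
            "sd_db": scenario.sl_spec.sd_bb,
            "slope_db_per_band": scenario.sl_spec.slope,
            "label": scenario.sl_spec.label,
        },
        "depth_model": {
            "mu": scenario.depth_params.mu,
            "sigma": scenario.depth_params.sigma,
            "z_max_m": scenario.depth_params.z_max,
        },
        "detection": {
            "dt_db": 5.0,
            "n_sl": 100,
            "n_depth": 100,
            "range_min_m": 10.0,
            "range_max_m": 100000.0,
            "n_ranges": 200,
            "percentiles": [25, 50, 75],
            "probability_marks": [0.1, 0.5, 0.9],
        },
        "pl_fit": {
            "depth_bin_min_m": 0.0,
            "depth_bin_max_m": scenario.depth_params.z_max,
            "depth_bin_width_m": scenario.truth.get("pl_fit", {}).get("depth_bin_width_m", 10.0),
            "r2_floor": 0.5,
            "pooling": "pooled",
        },
        "seed": scenario.seed,
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(scenario.truth, fh, indent=2, default=float)
    return {
        "ambient": ambient_path,
        "pl_samples": pl_path,
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.json",
    }
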
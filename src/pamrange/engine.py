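"""Monte Carlo detection-range engine.

For a caller at depth ``z`` emitting band source level ``SL(f)`` against
per-minute ambient noise ``NL(f)`` and fitted propagation-loss coefficients
``A(f, z)``, ``n(f, z)``, the per-band detection range follows from the
passive sonar equation with detection threshold ``DT``:

    R(f) = 10 ** ((A(f,z) + SL(f) - NL(f) - DT) / n(f,z))

The maximum detection range of a call is the maximum of ``R(f)`` over bands
(the band achieving it is the "argmax band"), and the detection-probability
curve for one realization is the survival function of the per-minute maxima:
P(r) = fraction of noise minutes whose maximum detection range is >= r.

A Monte Carlo ensemble draws a pool of broadband source levels and a pool of
caller depths and evaluates the full cross product (100 x 100 = 10,000
realizations by default), each realization producing one probability curve
over all minutes.  The ensemble is summarized by percentile envelopes
(25/50/75 by default), the per-band share of argmax outcomes, and median
detection ranges at configured probability marks (0.1/0.5/0.9).

All range arithmetic is carried in log10(range) — the closed form above is
evaluated once per (realization, minute, band); the range grid is used only
to sample curves and invert them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bands import AmbientSeries, BandScheme, NoiseStrata
from .depth import DepthModelParams, UniformDepthModel
from .propagation import PLFitTable
from .source_level import SourceLevelSpec, allocate_band_levels, sample_broadband_sl

__all__ = [
    "DetectionConfig",
    "DetectionCurveEnsemble",
    "Scenario",
    "SensitivityResult",
    "detection_range_band",
    "max_detection_range",
    "detection_curve",
    "median_range_at_probability",
    "run_monte_carlo",
    "run_stratified",
    "run_sensitivity",
    "write_ensemble_csvs",
]


def _default_range_grid() -> np.ndarray:
    # log-spaced 10 m .. 100 km; published site medians span ~90 m-37.5 km
    return np.logspace(1.0, 5.0, 200)


@dataclass
class DetectionConfig:
    """Knobs of the Monte Carlo detection-range computation.

    dt : detection threshold in dB (5 dB = reliable automated-detector SNR).
    n_sl, n_depth : source-level and depth pool sizes; the engine runs the
        full ``n_sl * n_depth`` cross product of realizations.
    cross_product : if False, draw ``n_sl * n_depth`` independent
        (source level, depth) pairs instead of crossing two pools.
    allocation_mode : how a broadband draw becomes band levels
        ("power" conserving, or "anchor_first").
    median_mode : how the headline median range is inverted
        ("percentile_curve" inverts the median envelope;
        "per_realization" takes the median of per-curve inversions).
    """

    dt: float = 5.0
    n_sl: int = 100
    n_depth: int = 100
    range_grid: np.ndarray = field(default_factory=_default_range_grid)
    percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)
    probability_marks: tuple[float, ...] = (0.1, 0.5, 0.9)
    seed: int = 0
    cross_product: bool = True
    allocation_mode: str = "power"
    median_mode: str = "percentile_curve"

    def __post_init__(self) -> None:
        self.range_grid = np.asarray(self.range_grid, dtype=float)
        if self.dt < 0:
            raise ValueError("detection threshold must be non-negative")
        if self.n_sl < 1 or self.n_depth < 1:
            raise ValueError("pool sizes must be at least 1")
        if np.any(self.range_grid <= 0) or np.any(np.diff(self.range_grid) <= 0):
            raise ValueError("range grid must be positive and strictly increasing")
        if self.median_mode not in ("percentile_curve", "per_realization"):
            raise ValueError(f"unknown median_mode {self.median_mode!r}")

    @property
    def n_realizations(self) -> int:
        return self.n_sl * self.n_depth


def detection_range_band(A, n, sl_band, nl_band, dt):
    """Per-band detection range ``10 ** ((A + SL - NL - DT) / n)`` in meters.

    Strictly increasing in ``A`` and ``sl_band``, strictly decreasing in
    ``nl_band`` and ``dt``; raising the noise by ``n`` dB divides the range
    by exactly 10.  Inputs broadcast.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("spreading coefficient n must be positive")
    out = 10.0 ** (
        (np.asarray(A, float) + np.asarray(sl_band, float)
         - np.asarray(nl_band, float) - float(dt)) / n
    )
    return float(out) if np.ndim(out) == 0 else out


def max_detection_range(per_band_ranges, usable=None) -> tuple[float, int]:
    """Maximum over usable bands and the (0-based) band index achieving it.

    Ties break toward the lowest band index.
    """
    r = np.asarray(per_band_ranges, dtype=float)
    if usable is None:
        usable = np.ones(r.shape, dtype=bool)
    usable = np.asarray(usable, dtype=bool)
    if not usable.any():
        raise ValueError("no usable band")
    masked = np.where(usable, r, -np.inf)
    idx = int(np.argmax(masked))  # argmax returns the first maximum
    return float(masked[idx]), idx


def detection_curve(r_max_per_minute, range_grid) -> np.ndarray:
    """Empirical survival function of per-minute maximum detection ranges.

    P(r) = #{minutes with Rmax >= r} / n_minutes, sampled on the grid.
    """
    r_max = np.asarray(r_max_per_minute, dtype=float)
    if r_max.size == 0:
        raise ValueError("need at least one minute")
    grid = np.asarray(range_grid, dtype=float)
    srt = np.sort(r_max)
    return (r_max.size - np.searchsorted(srt, grid, side="left")) / r_max.size


def _invert_curve(grid: np.ndarray, curve: np.ndarray, p: float) -> tuple[float, bool]:
    """Largest range where the curve is still >= p.

    Interpolates linearly in log10(range) between the bracketing grid
    points.  Returns (0, False) if the curve starts below p and
    (grid max, True) — the "unbounded" flag — if the curve never drops
    below p within the grid.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("probability mark must lie strictly in (0, 1)")
    above = curve >= p
    if not above[0]:
        return 0.0, False
    if above.all():
        return float(grid[-1]), True
    i = int(np.nonzero(above)[0][-1])
    lg = np.log10(grid)
    frac = (curve[i] - p) / (curve[i] - curve[i + 1])
    return float(10.0 ** (lg[i] + frac * (lg[i + 1] - lg[i]))), False


@dataclass
class DetectionCurveEnsemble:
    """Monte Carlo ensemble of detection-probability curves.

    curves : [n_realizations, n_ranges] probabilities, one row per
        (source level, depth) realization.
    percentile_curves : [n_percentiles, n_ranges] envelopes over realizations.
    argmax_band_share : per-band fraction of (realization, minute) outcomes
        in which that band set the maximum detection range (sums to 1).
    median_ranges : table (p_mark, percentile, range_m, unbounded) from
        inverting each percentile curve at each probability mark.
    """

    range_grid: np.ndarray
    curves: np.ndarray
    percentiles: tuple[float, ...]
    percentile_curves: np.ndarray
    argmax_band_share: np.ndarray
    median_ranges: pd.DataFrame
    config: DetectionConfig
    scheme: "BandScheme | None" = None

    @property
    def n_realizations(self) -> int:
        return self.curves.shape[0]


def median_range_at_probability(
    ensemble: DetectionCurveEnsemble, p: float, which: float | str = 50.0
) -> tuple[float, bool]:
    """Range at which the selected curve crosses probability ``p``.

    ``which`` selects a percentile envelope (e.g. 50.0 for the median curve)
    or ``"per_realization"`` to invert every realization curve and take the
    median of the resulting ranges (unbounded inversions enter at the grid
    maximum; the flag is set if at least half are unbounded).
    """
    if which == "per_realization":
        vals = np.empty(ensemble.n_realizations)
        flags = np.empty(ensemble.n_realizations, dtype=bool)
        for i in range(ensemble.n_realizations):
            vals[i], flags[i] = _invert_curve(ensemble.range_grid, ensemble.curves[i], p)
        return float(np.median(vals)), bool(np.mean(flags) >= 0.5)
    try:
        k = list(ensemble.percentiles).index(float(which))
    except ValueError as exc:
        raise ValueError(
            f"percentile {which} not in ensemble percentiles {ensemble.percentiles}"
        ) from exc
    return _invert_curve(ensemble.range_grid, ensemble.percentile_curves[k], p)


def _band_coeff_matrices(
    pl: PLFitTable, depths: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate (A, n) at each sampled depth for every usable band.

    Returns (usable_band_indices, A[n_depth, n_usable], n[n_depth, n_usable]).
    Bands without any usable cell are excluded with a one-time warning.
    """
    usable = pl.usable_bands()
    all_bands = np.arange(pl.scheme.n_bands)
    excluded = np.setdiff1d(all_bands, usable)
    if excluded.size:
        warnings.warn(
            f"excluding {excluded.size} band(s) with no usable propagation-loss "
            f"fit from the argmax: band indices {excluded.tolist()}",
            stacklevel=3,
        )
    if usable.size == 0:
        raise ValueError("all bands are unusable: no propagation-loss fits available")
    t = pl.table
    A = np.empty((depths.size, usable.size))
    n = np.empty((depths.size, usable.size))
    for j, b in enumerate(usable):
        cells = t[(t["band_index"] == b) & t["usable"]].sort_values("depth_bin_center_m")
        zc = cells["depth_bin_center_m"].to_numpy(dtype=float)
        A[:, j] = np.interp(depths, zc, cells["A_db"].to_numpy(dtype=float))
        n[:, j] = np.interp(depths, zc, cells["n"].to_numpy(dtype=float))
    return usable, A, n


def run_monte_carlo(
    noise: AmbientSeries,
    pl: PLFitTable,
    sl_spec: SourceLevelSpec,
    depth_model: DepthModelParams | UniformDepthModel,
    config: DetectionConfig | None = None,
) -> DetectionCurveEnsemble:
    """Full Monte Carlo detection-probability computation.

    Draws ``n_sl`` broadband source levels and ``n_depth`` caller depths
    from seeded substreams, crosses them into ``n_sl * n_depth``
    realizations, and for each realization evaluates the closed-form
    per-band detection range at every noise minute, reduces over bands to
    the per-minute maximum, and accumulates one survival curve.  One depth
    applies to all minutes of a realization (the depth belongs to the
    hypothetical caller, not to time).  Fully reproducible under
    ``config.seed``.
    """
    if config is None:
        config = DetectionConfig()
    if noise.scheme.n_bands != pl.scheme.n_bands or noise.scheme.f_low != pl.scheme.f_low:
        raise ValueError("ambient series and propagation-loss table use different band schemes")

    ss = np.random.SeedSequence(config.seed)
    child_sl, child_depth = ss.spawn(2)
    rng_sl = np.random.default_rng(child_sl)
    rng_depth = np.random.default_rng(child_depth)

    n_real = config.n_realizations
    if config.cross_product:
        sl_pool = sample_broadband_sl(sl_spec, config.n_sl, rng_sl)
        depth_pool = depth_model.sample(config.n_depth, rng_depth)
        sl_real = np.repeat(sl_pool, config.n_depth)          # SL varies outer
        depth_idx = np.tile(np.arange(config.n_depth), config.n_sl)
    else:
        sl_real = sample_broadband_sl(sl_spec, n_real, rng_sl)
        depth_pool = depth_model.sample(n_real, rng_depth)
        depth_idx = np.arange(n_real)

    usable, A_pool, n_pool = _band_coeff_matrices(pl, depth_pool)
    n_b = usable.size
    n_min = noise.n_minutes

    # band source levels over the FULL scheme (power is allocated across all
    # bands), then restricted to usable bands for the argmax
    sl_bands = allocate_band_levels(
        sl_real, sl_spec.slope, noise.scheme, mode=config.allocation_mode
    )[:, usable]

    nl = noise.spl[:, usable]                                 # (n_min, n_b)
    numer = A_pool[depth_idx] + sl_bands - config.dt          # (n_real, n_b)
    ncoef = n_pool[depth_idx]                                 # (n_real, n_b)

    grid = config.range_grid
    log_grid = np.log10(grid)
    curves = np.empty((n_real, grid.size))
    argmax_counts = np.zeros(noise.scheme.n_bands, dtype=np.int64)

    chunk = max(1, int(4_000_000 // max(1, n_min * n_b)))
    for start in range(0, n_real, chunk):
        stop = min(start + chunk, n_real)
        # log10 R for every (realization, minute, band)
        log_r = (numer[start:stop, None, :] - nl[None, :, :]) / ncoef[start:stop, None, :]
        arg = log_r.argmax(axis=2)                            # ties -> lowest index
        log_rmax = np.take_along_axis(log_r, arg[:, :, None], axis=2)[:, :, 0]
        argmax_counts += np.bincount(
            usable[arg.ravel()], minlength=noise.scheme.n_bands
        )
        for i in range(stop - start):
            srt = np.sort(log_rmax[i])
            curves[start + i] = (n_min - np.searchsorted(srt, log_grid, side="left")) / n_min

    percentile_curves = np.percentile(curves, config.percentiles, axis=0)
    share = argmax_counts / argmax_counts.sum()

    rows = []
    for p_mark in config.probability_marks:
        for k, pct in enumerate(config.percentiles):
            r, unbounded = _invert_curve(grid, percentile_curves[k], p_mark)
            rows.append((p_mark, pct, r, unbounded))
    median_ranges = pd.DataFrame(
        rows, columns=["p_mark", "percentile", "range_m", "unbounded"]
    )

    return DetectionCurveEnsemble(
        range_grid=grid,
        curves=curves,
        percentiles=tuple(config.percentiles),
        percentile_curves=percentile_curves,
        argmax_band_share=share,
        median_ranges=median_ranges,
        config=config,
        scheme=noise.scheme,
    )


def run_stratified(
    noise: AmbientSeries,
    strata: NoiseStrata,
    pl: PLFitTable,
    sl_spec: SourceLevelSpec,
    depth_model: DepthModelParams | UniformDepthModel,
    config: DetectionConfig | None = None,
) -> dict[str, DetectionCurveEnsemble]:
    """Re-run the Monte Carlo separately per noise stratum.

    All strata share the same seed, hence the same source-level and depth
    pools, so between-stratum differences isolate the noise effect.
    """
    out = {}
    for name, rows in strata.members.items():
        if len(rows) == 0:
            raise ValueError(f"noise stratum {name!r} is empty")
        out[name] = run_monte_carlo(noise.subset(rows), pl, sl_spec, depth_model, config)
    return out


@dataclass
class Scenario:
    """One complete model configuration: the four Monte Carlo factors plus knobs."""

    noise: AmbientSeries
    pl: PLFitTable
    sl_spec: SourceLevelSpec
    depth_model: DepthModelParams | UniformDepthModel
    config: DetectionConfig


@dataclass
class SensitivityResult:
    """Median-range difference when one factor is swapped (variant - base)."""

    factor: str
    median_a: float  # variant
    median_b: float  # base
    difference: float
    p_mark: float


_SWAP_FIELDS = {
    "source_level": "sl_spec",
    "noise": "noise",
    "propagation": "pl",
    "depth": "depth_model",
}


def run_sensitivity(
    base: Scenario,
    swaps: list[dict],
    p_mark: float = 0.5,
    which: float | str = 50.0,
) -> list[SensitivityResult]:
    """Factor-swap sensitivity analysis.

    Each swap is a one-entry mapping ``{factor: replacement}`` with factor in
    ``source_level | noise | propagation | depth``; exactly one factor may
    change per swap.  Base and variant runs share the seed, so swapping a
    factor for itself yields a difference of exactly 0.
    """
    base_ens = run_monte_carlo(
        base.noise, base.pl, base.sl_spec, base.depth_model, base.config
    )
    median_b, _ = median_range_at_probability(base_ens, p_mark, which)

    results = []
    for swap in swaps:
        if len(swap) != 1:
            raise ValueError(
                f"each swap must change exactly one factor, got keys {sorted(swap)}"
            )
        (factor, value), = swap.items()
        if factor not in _SWAP_FIELDS:
            raise ValueError(
                f"unknown factor {factor!r}; expected one of {sorted(_SWAP_FIELDS)}"
            )
        variant = replace(base, **{_SWAP_FIELDS[factor]: value})
        ens = run_monte_carlo(
            variant.noise, variant.pl, variant.sl_spec, variant.depth_model, variant.config
        )
        median_a, _ = median_range_at_probability(ens, p_mark, which)
        results.append(
            SensitivityResult(
                factor=factor,
                median_a=median_a,
                median_b=median_b,
                difference=median_a - median_b,
                p_mark=p_mark,
            )
        )
    return results


def write_ensemble_csvs(ensemble: DetectionCurveEnsemble, outdir, prefix: str = "") -> dict:
    """Write the summary, median-range, and argmax-histogram CSVs.

    Returns the mapping of artifact name to path.  The summary CSV has one
    ``p<percentile>`` column per configured percentile (p25, p50, p75 by
    default).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = pd.DataFrame({"range_m": ensemble.range_grid})
    for k, pct in enumerate(ensemble.percentiles):
        summary[f"p{pct:g}"] = ensemble.percentile_curves[k]
    p = outdir / f"{prefix}ensemble_summary.csv"
    summary.to_csv(p, index=False, float_format="%.6f")
    paths["ensemble_summary"] = p

    p = outdir / f"{prefix}median_ranges.csv"
    ensemble.median_ranges.to_csv(p, index=False, float_format="%.6f")
    paths["median_ranges"] = p

    hist = pd.DataFrame(
        {
            "band_index": np.arange(ensemble.argmax_band_share.size),
            "share": ensemble.argmax_band_share,
        }
    )
    if ensemble.scheme is not None:
        edges = ensemble.scheme.edges
        hist.insert(0, "band_low_hz", edges[:-1])
        hist.insert(1, "band_high_hz", edges[1:])
    p = outdir / f"{prefix}argmax_band_histogram.csv"
    hist.to_csv(p, index=False, float_format="%.6f")
    paths["argmax_band_histogram"] = p
    return paths
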
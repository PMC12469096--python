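"""Frequency-band tiling and per-minute ambient band levels.

The detection model works on a contiguous tiling of the call's frequency span
into equal-width bands (300 Hz wide, 1000-14800 Hz for killer whale pulsed
calls, i.e. 46 bands).  Ambient noise enters the model as a minutes x bands
matrix of band sound pressure levels (SPL, dB re 1 uPa); this module defines
those containers, computes band levels from calibrated audio, reduces band
levels to broadband power sums, and partitions minutes into low / medium /
high noise strata by broadband terciles.

Band membership is half-open ``[low, high)`` except the final band, which is
closed at the upper scheme edge, so the tiling never double-counts energy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "BandScheme",
    "AmbientSeries",
    "NoiseStrata",
    "make_band_scheme",
    "broadband_level",
    "band_spl_from_audio",
    "stratify_by_broadband",
    "read_ambient_csv",
    "write_ambient_csv",
]


@dataclass(frozen=True)
class BandScheme:
    """Contiguous equal-width frequency tiling.

    Parameters
    ----------
    f_low, f_high : float
        Scheme edges in Hz; the span must be an exact multiple of ``width``.
    width : float
        Band width in Hz.
    """

    f_low: float
    f_high: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.f_low >= self.f_high:
            raise ValueError(
                f"f_low ({self.f_low}) must be below f_high ({self.f_high})"
            )
        span = self.f_high - self.f_low
        remainder = span % self.width
        if remainder != 0:
            raise ValueError(
                f"span {span} Hz is not divisible by width {self.width} Hz "
                f"(remainder {remainder} Hz)"
            )

    @property
    def n_bands(self) -> int:
        return int(round((self.f_high - self.f_low) / self.width))

    @property
    def edges(self) -> np.ndarray:
        """Band boundaries, length ``n_bands + 1``, strictly increasing."""
        return self.f_low + self.width * np.arange(self.n_bands + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.f_low + self.width * (np.arange(self.n_bands) + 0.5)

    def band_columns(self) -> list[str]:
        """Column names ``spl_<low>_<high>`` used in the ambient CSV format."""
        e = self.edges
        return [f"spl_{int(e[i])}_{int(e[i + 1])}" for i in range(self.n_bands)]


def make_band_scheme(f_low: float, f_high: float, width: float) -> BandScheme:
    """Build the contiguous band tiling covering ``[f_low, f_high]``.

    The default analysis scheme for killer whale pulsed calls is
    ``make_band_scheme(1000, 14800, 300)`` -> 46 bands.
    """
    return BandScheme(float(f_low), float(f_high), float(width))


#: The 46-band scheme used for killer whale pulsed calls (1000-14800 Hz, 300 Hz).
KILLER_WHALE_SCHEME = make_band_scheme(1000.0, 14800.0, 300.0)


def broadband_level(band_spls) -> float:
    """Power-sum reduction of band SPLs to a single broadband SPL.

    ``10 * log10(sum_i 10^(SPL_i / 10))``.  Always at least the loudest band.
    """
    levels = np.asarray(band_spls, dtype=float)
    if levels.size == 0:
        raise ValueError("broadband_level requires at least one band level")
    if not np.all(np.isfinite(levels)):
        raise ValueError("broadband_level requires finite band levels")
    # log-sum-exp in base 10 for numerical safety at high levels
    m = levels.max()
    return float(m + 10.0 * np.log10(np.sum(10.0 ** ((levels - m) / 10.0))))


@dataclass
class AmbientSeries:
    """Minute-resolved ambient band levels: the NL(f) time series.

    ``spl`` is an ``[n_minutes, n_bands]`` matrix of band SPL in dB re 1 uPa.
    Timestamps are opaque ordered labels (ISO-8601 text when read from CSV);
    no timezone logic is applied.
    """

    timestamps: np.ndarray
    spl: np.ndarray
    scheme: BandScheme
    site_label: str = ""
    season_label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps)
        self.spl = np.atleast_2d(np.asarray(self.spl, dtype=float))
        if self.spl.shape[1] != self.scheme.n_bands:
            raise ValueError(
                f"spl has {self.spl.shape[1]} band columns, scheme expects "
                f"{self.scheme.n_bands}"
            )
        if self.spl.shape[0] != self.timestamps.shape[0]:
            raise ValueError("timestamps and spl row counts differ")
        if not np.all(np.isfinite(self.spl)):
            raise ValueError("ambient SPL matrix contains non-finite values")
        if len(np.unique(self.timestamps)) != len(self.timestamps):
            raise ValueError("timestamps must be unique")

    @property
    def n_minutes(self) -> int:
        return self.spl.shape[0]

    def broadband(self) -> np.ndarray:
        """Per-minute broadband SPL (power sum over bands)."""
        m = self.spl.max(axis=1, keepdims=True)
        return (m + 10.0 * np.log10(
            np.sum(10.0 ** ((self.spl - m) / 10.0), axis=1, keepdims=True)
        )).ravel()

    def subset(self, rows: np.ndarray) -> "AmbientSeries":
        """New series restricted to the given minute indices."""
        return AmbientSeries(
            timestamps=self.timestamps[rows],
            spl=self.spl[rows],
            scheme=self.scheme,
            site_label=self.site_label,
            season_label=self.season_label,
        )


@dataclass
class NoiseStrata:
    """Tercile partition of minutes by broadband level.

    ``thresholds`` are the (lower, upper) broadband SPL cut points;
    ``members`` maps ``low`` / ``medium`` / ``high`` to minute-index arrays.
    """

    thresholds: tuple[float, float]
    members: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if lo > hi:
            raise ValueError("lower threshold exceeds upper threshold")


def stratify_by_broadband(
    series: AmbientSeries, probs: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
) -> NoiseStrata:
    """Partition minutes into low / medium / high ambient-noise conditions.

    Thresholds are empirical quantiles (default the 33rd and 66th percentiles)
    of the per-minute broadband level so that each condition is represented
    equally.  Minutes strictly below the lower threshold are *low*, strictly
    above the upper threshold are *high*, everything else (ties included) is
    *medium*.
    """
    if series.n_minutes < 3:
        raise ValueError("need at least 3 minutes to form three noise strata")
    p_lo, p_hi = probs
    if not (0.0 < p_lo <= p_hi < 1.0):
        raise ValueError(f"stratum fractions must satisfy 0 < lo <= hi < 1, got {probs}")
    bb = series.broadband()
    lo, hi = np.quantile(bb, [p_lo, p_hi])
    idx = np.arange(series.n_minutes)
    low = idx[bb < lo]
    high = idx[bb > hi]
    medium = idx[(bb >= lo) & (bb <= hi)]
    return NoiseStrata(
        thresholds=(float(lo), float(hi)),
        members={"low": low, "medium": medium, "high": high},
    )


def band_spl_from_audio(
    waveform,
    sample_rate: float,
    scheme: BandScheme,
    *,
    sensitivity_db: float = 0.0,
    gain_db: float = 0.0,
    window_s: float = 60.0,
    silence: str = "error",
    site_label: str = "",
    season_label: str = "",
) -> AmbientSeries:
    """Compute per-window band SPL from a single-channel recording.

    The waveform is converted to pressure (uPa) using the hydrophone
    sensitivity (dB re 1 V/uPa) and gain (dB); a waveform already calibrated
    in uPa uses the defaults ``sensitivity_db = gain_db = 0``.  Each full
    averaging window (default 60 s) yields one row: band SPL is 10*log10 of
    the mean-square pressure contributed by that band, obtained by
    integrating a Welch PSD (1 s Hann segments, 50% overlap) across the band
    edges.  Partial trailing windows are discarded.

    ``silence`` controls bands with zero power: ``"error"`` raises,
    ``"floor"`` emits -120 dB.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("zero-length audio")
    if sample_rate <= 2.0 * scheme.f_high:
        raise ValueError(
            f"sample rate {sample_rate} Hz violates Nyquist for f_high "
            f"{scheme.f_high} Hz (need > {2 * scheme.f_high} Hz)"
        )
    if silence not in ("error", "floor"):
        raise ValueError("silence policy must be 'error' or 'floor'")

    # volts -> uPa: p = v * 10^(-(sensitivity+gain)/20)
    pressure = x * 10.0 ** (-(sensitivity_db + gain_db) / 20.0)

    n_win = int(round(window_s * sample_rate))
    n_windows = pressure.size // n_win
    if n_windows < 1:
        raise ValueError(
            f"recording shorter than one averaging window ({window_s} s)"
        )

    nperseg = min(int(round(sample_rate)), n_win)  # 1 s analysis segments
    edges = scheme.edges
    rows = np.empty((n_windows, scheme.n_bands))
    for w in range(n_windows):
        seg = pressure[w * n_win : (w + 1) * n_win]
        freqs, psd = _signal.welch(
            seg,
            fs=sample_rate,
            window="hann",
            nperseg=nperseg,
            noverlap=nperseg // 2,
            detrend="constant",
            scaling="density",
        )
        df = freqs[1] - freqs[0]
        for b in range(scheme.n_bands):
            if b < scheme.n_bands - 1:
                mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
            else:  # final band closed at f_high
                mask = (freqs >= edges[b]) & (freqs <= edges[b + 1])
            ms = psd[mask].sum() * df  # mean-square pressure in band, uPa^2
            if ms <= 0.0:
                if silence == "error":
                    raise ValueError(
                        f"zero band power in window {w}, band {b} "
                        "(digital silence); pass silence='floor' to emit "
                        "-120 dB instead"
                    )
                rows[w, b] = -120.0
            else:
                rows[w, b] = 10.0 * np.log10(ms)

    timestamps = np.array([f"w{w:06d}" for w in range(n_windows)])
    return AmbientSeries(
        timestamps=timestamps,
        spl=rows,
        scheme=scheme,
        site_label=site_label,
        season_label=season_label,
    )


def write_ambient_csv(series: AmbientSeries, path) -> None:
    """Write an AmbientSeries to CSV (4-decimal SPLs, ``#`` metadata header)."""
    cols = series.scheme.band_columns()
    df = pd.DataFrame(series.spl, columns=cols)
    df.insert(0, "timestamp", series.timestamps)
    with open(path, "w") as fh:
        fh.write(f"# site={series.site_label}\n")
        fh.write(f"# season={series.season_label}\n")
        fh.write(
            f"# scheme={series.scheme.f_low:g},{series.scheme.f_high:g},"
            f"{series.scheme.width:g}\n"
        )
        df.to_csv(fh, index=False, float_format="%.4f")


def read_ambient_csv(path, scheme: BandScheme | None = None) -> AmbientSeries:
    """Read an ambient band-level CSV written by :func:`write_ambient_csv`.

    The header's ``spl_<low>_<high>`` columns must match ``scheme``; if
    ``scheme`` is None it is reconstructed from the ``# scheme=`` comment or
    from the columns themselves.
    """
    site = season = ""
    scheme_meta: BandScheme | None = None
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("site="):
                    site = meta[5:]
                elif meta.startswith("season="):
                    season = meta[7:]
                elif meta.startswith("scheme="):
                    lo, hi, w = (float(v) for v in meta[7:].split(","))
                    scheme_meta = make_band_scheme(lo, hi, w)
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body)
    if "timestamp" not in df.columns:
        raise ValueError("malformed ambient CSV: missing 'timestamp' column")
    band_cols = [c for c in df.columns if c.startswith("spl_")]
    if not band_cols:
        raise ValueError("malformed ambient CSV: no 'spl_<low>_<high>' columns")

    if scheme is None:
        if scheme_meta is not None:
            scheme = scheme_meta
        else:  # reconstruct from column names
            try:
                bounds = [tuple(map(float, c[4:].split("_"))) for c in band_cols]
            except ValueError as exc:
                raise ValueError(f"malformed band column names: {exc}") from exc
            scheme = make_band_scheme(
                bounds[0][0], bounds[-1][1], bounds[0][1] - bounds[0][0]
            )
    expected = scheme.band_columns()
    if band_cols != expected:
        raise ValueError(
            f"band columns do not match scheme: expected {len(expected)} "
            f"columns {expected[0]}..{expected[-1]}, found {len(band_cols)}"
        )
    return AmbientSeries(
        timestamps=df["timestamp"].to_numpy(),
        spl=df[band_cols].to_numpy(dtype=float),
        scheme=scheme,
        site_label=site,
        season_label=season,
    )
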
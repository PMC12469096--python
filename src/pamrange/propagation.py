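"""Log-range propagation-loss fits.

Propagation loss between a caller and the hydrophone is modeled, per
frequency band and source-depth bin, by the empirical log law

    PL(f, z, R) = A(f, z) - n(f, z) * log10(R)

with intercept ``A`` (dB at R = 1 m) and spreading coefficient ``n``
(20 = spherical, 10 = cylindrical spreading).  The coefficients are fit by
ordinary least squares to PL samples exported from any external propagation
model; this module never models propagation itself, it only fits and
evaluates the log law.  Cells with fewer than two distinct ranges, a
non-positive spreading coefficient, or a coefficient of determination below
a configurable floor are flagged unusable rather than silently kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandScheme

__all__ = [
    "PLSampleTable",
    "PLFitTable",
    "fit_pl_loglaw",
    "pl_coeffs_at",
    "pl_at",
    "read_pl_samples_csv",
    "write_pl_samples_csv",
    "read_pl_fit_csv",
    "write_pl_fit_csv",
]

SAMPLE_COLUMNS = ["range_m", "source_depth_m", "band_index", "pl_db", "transect_id"]


@dataclass
class PLSampleTable:
    """Propagation-loss samples: (range, source depth, band, PL[, transect]).

    ``data`` columns: ``range_m`` (> 0), ``source_depth_m``, ``band_index``
    (0-based, valid for the attached scheme), ``pl_db`` (finite),
    ``transect_id`` (optional label; a single default transect otherwise).
    """

    data: pd.DataFrame
    scheme: BandScheme

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "transect_id" not in df.columns:
            df["transect_id"] = "t0"
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"PL sample table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("PL sample table is empty")
        if (df["range_m"] <= 0).any():
            raise ValueError("PL sample ranges must be positive")
        if not np.isfinite(df["pl_db"]).all():
            raise ValueError("PL samples contain non-finite values")
        bad = ~df["band_index"].between(0, self.scheme.n_bands - 1)
        if bad.any():
            raise ValueError(
                f"band_index out of range for scheme with {self.scheme.n_bands} bands"
            )
        self.data = df[SAMPLE_COLUMNS]


@dataclass
class PLFitTable:
    """Fitted (A, n) per band x depth bin, with OLS diagnostics.

    ``table`` columns: ``band_index``, ``depth_bin_center_m``, ``A_db``,
    ``n``, ``r2``, ``rmse_db``, ``n_samples``, ``usable``.  Every
    (band, depth-bin) cell present in the input is either fitted or
    explicitly marked unusable.
    """

    table: pd.DataFrame
    scheme: BandScheme
    depth_bin_centers: np.ndarray

    def usable_bands(self) -> np.ndarray:
        """0-based indices of bands with at least one usable depth cell."""
        t = self.table
        return np.unique(t.loc[t["usable"], "band_index"].to_numpy(dtype=int))


def _ols_loglaw(ranges: np.ndarray, pl: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of pl on log10(range); returns (A, n, r2, rmse)."""
    x = np.log10(ranges)
    slope, intercept = np.polyfit(x, pl, 1)
    resid = pl - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((pl - pl.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(pl)))
    return float(intercept), float(-slope), r2, rmse


def fit_pl_loglaw(
    samples: PLSampleTable,
    scheme: BandScheme,
    depth_bins: np.ndarray | None = None,
    pooling: str = "pooled",
    r2_floor: float = 0.5,
) -> PLFitTable:
    """Fit ``pl = A - n*log10(R)`` per (band, source-depth bin).

    Parameters
    ----------
    depth_bins : array
        Depth bin edges in m (default 0-200 m in 10 m bins).  Samples
        outside the edges are dropped with a warning.
    pooling : {"pooled", "per_transect"}
        ``pooled`` fits all transects of a cell jointly (default);
        ``per_transect`` fits each transect separately and aggregates
        coefficients by median.  With a single transect both are identical.
    r2_floor : float
        Cells with r2 below this floor (or n <= 0, or < 2 distinct ranges)
        are flagged unusable.
    """
    if scheme.n_bands != samples.scheme.n_bands or scheme.edges[0] != samples.scheme.edges[0]:
        raise ValueError("sample table scheme does not match the requested scheme")
    if pooling not in ("pooled", "per_transect"):
        raise ValueError(f"unknown pooling policy {pooling!r}")
    if depth_bins is None:
        depth_bins = np.arange(0.0, 200.0 + 10.0, 10.0)
    depth_bins = np.asarray(depth_bins, dtype=float)
    centers = 0.5 * (depth_bins[:-1] + depth_bins[1:])

    df = samples.data
    z = df["source_depth_m"].to_numpy(dtype=float)
    in_span = (z >= depth_bins[0]) & (z <= depth_bins[-1])
    if not in_span.all():
        warnings.warn(
            f"dropping {np.sum(~in_span)} PL samples outside the depth-bin span",
            stacklevel=2,
        )
        df = df[in_span]
        z = z[in_span]
    # right-closed final bin so z == depth_bins[-1] stays in the last bin
    bin_idx = np.clip(np.digitize(z, depth_bins) - 1, 0, len(centers) - 1)
    df = df.assign(_bin=bin_idx)

    rows = []
    for (band, b), cell in df.groupby(["band_index", "_bin"]):
        ranges = cell["range_m"].to_numpy(dtype=float)
        pl = cell["pl_db"].to_numpy(dtype=float)
        n_distinct = len(np.unique(ranges))
        if n_distinct < 2:
            rows.append((band, centers[b], np.nan, np.nan, np.nan, np.nan, len(cell), False))
            continue
        if pooling == "pooled" or cell["transect_id"].nunique() == 1:
            A, n, r2, rmse = _ols_loglaw(ranges, pl)
        else:
            fits = []
            for _, tcell in cell.groupby("transect_id"):
                tr = tcell["range_m"].to_numpy(dtype=float)
                if len(np.unique(tr)) < 2:
                    continue
                fits.append(_ols_loglaw(tr, tcell["pl_db"].to_numpy(dtype=float)))
            if not fits:
                rows.append((band, centers[b], np.nan, np.nan, np.nan, np.nan, len(cell), False))
                continue
            arr = np.array(fits)
            A, n, r2, rmse = (float(np.median(arr[:, k])) for k in range(4))
        usable = (n > 0) and (r2 >= r2_floor)
        rows.append((band, centers[b], A, n, r2, rmse, len(cell), usable))

    if not rows:
        raise ValueError("no PL samples fall inside the depth-bin span")
    table = pd.DataFrame(
        rows,
        columns=[
            "band_index",
            "depth_bin_center_m",
            "A_db",
            "n",
            "r2",
            "rmse_db",
            "n_samples",
            "usable",
        ],
    ).sort_values(["band_index", "depth_bin_center_m"], ignore_index=True)
    return PLFitTable(table=table, scheme=scheme, depth_bin_centers=centers)


def pl_coeffs_at(table: PLFitTable, band_index: int, z: float) -> tuple[float, float]:
    """(A, n) for a band at source depth ``z``.

    Linear interpolation in the usable depth-bin centers; clamped to the
    nearest fitted bin outside the fitted span.
    """
    t = table.table
    cells = t[(t["band_index"] == band_index) & t["usable"]]
    if len(cells) == 0:
        raise ValueError(f"band {band_index} has no usable propagation-loss fit")
    zc = cells["depth_bin_center_m"].to_numpy(dtype=float)
    order = np.argsort(zc)
    zc = zc[order]
    A = np.interp(z, zc, cells["A_db"].to_numpy(dtype=float)[order])
    n = np.interp(z, zc, cells["n"].to_numpy(dtype=float)[order])
    return float(A), float(n)


def pl_at(table: PLFitTable, band_index: int, z: float, R) -> float | np.ndarray:
    """Evaluate ``PL = A - n*log10(R)`` at source depth ``z`` and range ``R`` (m)."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("range must be positive")
    A, n = pl_coeffs_at(table, band_index, z)
    out = A - n * np.log10(R)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV formats


def write_pl_samples_csv(samples: PLSampleTable, path) -> None:
    """Columns: range_m, source_depth_m, band_low_hz, band_high_hz, pl_db, transect_id."""
    edges = samples.scheme.edges
    df = samples.data.copy()
    bi = df["band_index"].to_numpy(dtype=int)
    df["band_low_hz"] = edges[bi]
    df["band_high_hz"] = edges[bi + 1]
    cols = ["range_m", "source_depth_m", "band_low_hz", "band_high_hz", "pl_db", "transect_id"]
    df[cols].to_csv(path, index=False, float_format="%.6f")


def read_pl_samples_csv(path, scheme: BandScheme) -> PLSampleTable:
    df = pd.read_csv(path)
    required = ["range_m", "source_depth_m", "band_low_hz", "band_high_hz", "pl_db"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PL sample CSV missing columns: {missing}")
    band_index = np.rint((df["band_low_hz"] - scheme.f_low) / scheme.width).astype(int)
    if not np.allclose(scheme.f_low + band_index * scheme.width, df["band_low_hz"]):
        raise ValueError("band_low_hz values do not align with the band scheme")
    df = df.assign(band_index=band_index)
    return PLSampleTable(data=df, scheme=scheme)


def write_pl_fit_csv(table: PLFitTable, path) -> None:
    """Columns: band_low_hz, band_high_hz, depth_bin_center_m, A_db, n, r2, rmse_db, n_samples, usable."""
    edges = table.scheme.edges
    df = table.table.copy()
    bi = df["band_index"].to_numpy(dtype=int)
    df["band_low_hz"] = edges[bi]
    df["band_high_hz"] = edges[bi + 1]
    cols = [
        "band_low_hz",
        "band_high_hz",
        "depth_bin_center_m",
        "A_db",
        "n",
        "r2",
        "rmse_db",
        "n_samples",
        "usable",
    ]
    df[cols].to_csv(path, index=False, float_format="%.6f")


def read_pl_fit_csv(path, scheme: BandScheme) -> PLFitTable:
    df = pd.read_csv(path)
    band_index = np.rint((df["band_low_hz"] - scheme.f_low) / scheme.width).astype(int)
    df = df.assign(band_index=band_index)
    centers = np.unique(df["depth_bin_center_m"].to_numpy(dtype=float))
    cols = [
        "band_index",
        "depth_bin_center_m",
        "A_db",
        "n",
        "r2",
        "rmse_db",
        "n_samples",
        "usable",
    ]
    return PLFitTable(table=df[cols], scheme=scheme, depth_bin_centers=centers)
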
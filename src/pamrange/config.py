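"""Run configuration: YAML schema, validation, and object construction.

A run config collects everything a simulation needs: input paths, the band
scheme, the source-level and depth models, the detection knobs, and the
propagation-loss fit settings.  Defaults equal the standard killer whale
analysis constants (DT = 5 dB, 46 bands 1000-14800 Hz, 100 x 100 Monte
Carlo pools, percentiles 25/50/75, probability marks 0.1/0.5/0.9).  The
config is validated before any computation; errors list the offending keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bands import BandScheme, make_band_scheme
from .depth import DepthModelParams, UniformDepthModel
from .engine import DetectionConfig
from .source_level import SourceLevelSpec

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message lists the offending keys."""


@dataclass
class RunConfig:
    scheme: BandScheme
    sl_spec: SourceLevelSpec
    depth_model: DepthModelParams | UniformDepthModel
    detection: DetectionConfig
    ambient_csv: Path | None = None
    pl_samples_csv: Path | None = None
    pl_fit_csv: Path | None = None
    site_label: str = ""
    season_label: str = ""
    depth_bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 210.0, 10.0)
    )
    r2_floor: float = 0.5
    pooling: str = "pooled"
    swaps: list[dict] = field(default_factory=list)
    raw: dict = field(default_factory=dict)


_NUMERIC = (int, float)


def _require(section: dict, name: str, keys: dict, errors: list, optional=()) -> None:
    """Check presence and types; ``keys`` maps key -> expected type tuple."""
    if not isinstance(section, dict):
        errors.append(f"{name}: expected a mapping")
        return
    for key, typ in keys.items():
        if key not in section:
            if key in optional:
                continue
            errors.append(f"{name}.{key}: missing")
        elif not isinstance(section[key], typ):
            errors.append(
                f"{name}.{key}: expected {typ[0].__name__ if isinstance(typ, tuple) else typ.__name__}, "
                f"got {type(section[key]).__name__}"
            )
    unknown = set(section) - set(keys)
    if unknown:
        errors.append(f"{name}: unknown keys {sorted(unknown)}")


def parse_config(cfg: dict, base_dir: Path | str = ".") -> RunConfig:
    """Validate a config mapping and build a :class:`RunConfig`.

    Relative input paths are resolved against ``base_dir`` (normally the
    config file's directory).  Raises :class:`ConfigError` listing every
    offending key at once.
    """
    base_dir = Path(base_dir)
    errors: list[str] = []
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")

    known_sections = {
        "site", "inputs", "band_scheme", "source_level", "depth_model",
        "detection", "pl_fit", "sensitivity", "seed", "output_dir",
    }
    unknown = set(cfg) - known_sections
    if unknown:
        errors.append(f"config: unknown sections {sorted(unknown)}")

    bs = cfg.get("band_scheme", {"f_low_hz": 1000.0, "f_high_hz": 14800.0, "width_hz": 300.0})
    _require(bs, "band_scheme", {"f_low_hz": _NUMERIC, "f_high_hz": _NUMERIC, "width_hz": _NUMERIC}, errors)

    sl = cfg.get("source_level")
    if sl is None:
        errors.append("source_level: missing")
    else:
        _require(
            sl, "source_level",
            {"mean_db": _NUMERIC, "sd_db": _NUMERIC, "slope_db_per_band": _NUMERIC, "label": (str,)},
            errors, optional=("label",),
        )

    dm = cfg.get("depth_model")
    if dm is None:
        errors.append("depth_model: missing")
    elif isinstance(dm, dict) and "uniform_z_max_m" in dm:
        _require(dm, "depth_model", {"uniform_z_max_m": _NUMERIC}, errors)
    else:
        _require(dm, "depth_model", {"mu": _NUMERIC, "sigma": _NUMERIC, "z_max_m": _NUMERIC}, errors)

    det = cfg.get("detection", {})
    _require(
        det, "detection",
        {
            "dt_db": _NUMERIC, "n_sl": (int,), "n_depth": (int,),
            "range_min_m": _NUMERIC, "range_max_m": _NUMERIC, "n_ranges": (int,),
            "percentiles": (list,), "probability_marks": (list,),
            "cross_product": (bool,), "allocation_mode": (str,), "median_mode": (str,),
        },
        errors,
        optional=(
            "dt_db", "n_sl", "n_depth", "range_min_m", "range_max_m", "n_ranges",
            "percentiles", "probability_marks", "cross_product", "allocation_mode",
            "median_mode",
        ),
    )

    plf = cfg.get("pl_fit", {})
    _require(
        plf, "pl_fit",
        {
            "depth_bin_min_m": _NUMERIC, "depth_bin_max_m": _NUMERIC,
            "depth_bin_width_m": _NUMERIC, "r2_floor": _NUMERIC, "pooling": (str,),
        },
        errors,
        optional=("depth_bin_min_m", "depth_bin_max_m", "depth_bin_width_m", "r2_floor", "pooling"),
    )

    inputs = cfg.get("inputs", {})
    _require(
        inputs, "inputs",
        {"ambient_csv": (str,), "pl_samples_csv": (str,), "pl_fit_csv": (str,)},
        errors, optional=("ambient_csv", "pl_samples_csv", "pl_fit_csv"),
    )

    seed = cfg.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: expected int")

    swaps = cfg.get("sensitivity", [])
    if not isinstance(swaps, list):
        errors.append("sensitivity: expected a list of single-factor swaps")
        swaps = []
    else:
        valid_factors = {"source_level", "noise", "propagation", "depth"}
        for i, swap in enumerate(swaps):
            if not isinstance(swap, dict) or len(swap) != 1:
                errors.append(
                    f"sensitivity[{i}]: each swap must change exactly one factor, "
                    f"got {sorted(swap) if isinstance(swap, dict) else swap}"
                )
            elif next(iter(swap)) not in valid_factors:
                errors.append(
                    f"sensitivity[{i}]: unknown factor {next(iter(swap))!r}; "
                    f"expected one of {sorted(valid_factors)}"
                )

    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))

    scheme = make_band_scheme(bs["f_low_hz"], bs["f_high_hz"], bs["width_hz"])
    sl_spec = SourceLevelSpec(
        mean_bb=float(sl["mean_db"]), sd_bb=float(sl["sd_db"]),
        slope=float(sl["slope_db_per_band"]), label=str(sl.get("label", "")),
    )
    if "uniform_z_max_m" in dm:
        depth_model: DepthModelParams | UniformDepthModel = UniformDepthModel(
            z_max=float(dm["uniform_z_max_m"])
        )
    else:
        depth_model = DepthModelParams(
            mu=float(dm["mu"]), sigma=float(dm["sigma"]), z_max=float(dm["z_max_m"])
        )

    detection = DetectionConfig(
        dt=float(det.get("dt_db", 5.0)),
        n_sl=int(det.get("n_sl", 100)),
        n_depth=int(det.get("n_depth", 100)),
        range_grid=np.logspace(
            np.log10(float(det.get("range_min_m", 10.0))),
            np.log10(float(det.get("range_max_m", 100000.0))),
            int(det.get("n_ranges", 200)),
        ),
        percentiles=tuple(float(p) for p in det.get("percentiles", [25, 50, 75])),
        probability_marks=tuple(float(p) for p in det.get("probability_marks", [0.1, 0.5, 0.9])),
        seed=seed,
        cross_product=bool(det.get("cross_product", True)),
        allocation_mode=str(det.get("allocation_mode", "power")),
        median_mode=str(det.get("median_mode", "percentile_curve")),
    )

    lo = float(plf.get("depth_bin_min_m", 0.0))
    hi = float(plf.get("depth_bin_max_m", 200.0))
    w = float(plf.get("depth_bin_width_m", 10.0))
    edges = np.arange(lo, hi + w, w)

    site = cfg.get("site", {}) or {}

    def _resolve(key):
        return (base_dir / inputs[key]) if key in inputs else None

    return RunConfig(
        scheme=scheme,
        sl_spec=sl_spec,
        depth_model=depth_model,
        detection=detection,
        ambient_csv=_resolve("ambient_csv"),
        pl_samples_csv=_resolve("pl_samples_csv"),
        pl_fit_csv=_resolve("pl_fit_csv"),
        site_label=str(site.get("label", "")),
        season_label=str(site.get("season", "")),
        depth_bin_edges=edges,
        r2_floor=float(plf.get("r2_floor", 0.5)),
        pooling=str(plf.get("pooling", "pooled")),
        swaps=swaps,
        raw=cfg,
    )


def load_config(path) -> RunConfig:
    """Read and validate a YAML run config; paths resolve against its directory."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return parse_config(cfg, base_dir=path.parent)
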
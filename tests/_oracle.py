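"""Naive brute-force references, deliberately loop-based and grid-based.

The production engine evaluates the per-band detection range in closed form
and never loops over grid ranges; these oracles do the opposite: they test
the detection condition "received band level exceeds noise plus threshold"
at every (realization, minute, band, grid range) through ``pl_at``, and
count minutes.  Agreement between the two routes is the core correctness
check for the Monte Carlo engine.
"""

import numpy as np

from pamrange.propagation import PLFitTable, pl_at


def brute_force_curves(
    nl: np.ndarray,
    pl_table: PLFitTable,
    sl_bands: np.ndarray,
    depths: np.ndarray,
    usable_bands: np.ndarray,
    dt: float,
    grid: np.ndarray,
) -> np.ndarray:
    """Detection-probability curves by exhaustive looping.

    nl : [n_minutes, n_bands_full] ambient band levels.
    sl_bands : [n_real, n_bands_full] per-realization band source levels.
    depths : [n_real] caller depth per realization.
    usable_bands : indices of bands participating in the argmax.
    Returns [n_real, n_grid] probabilities.
    """
    n_real = sl_bands.shape[0]
    n_min = nl.shape[0]
    curves = np.zeros((n_real, grid.size))
    for i in range(n_real):
        for g, r in enumerate(grid):
            detected = 0
            for m in range(n_min):
                hit = False
                for b in usable_bands:
                    received = sl_bands[i, b] + pl_at(pl_table, int(b), float(depths[i]), float(r))
                    if received >= nl[m, b] + dt:
                        hit = True
                        break
                if hit:
                    detected += 1
            curves[i, g] = detected / n_min
    return curves


def brute_force_rmax(
    nl_row: np.ndarray,
    pl_table: PLFitTable,
    sl_row: np.ndarray,
    depth: float,
    usable_bands: np.ndarray,
    dt: float,
) -> tuple[float, int]:
    """Per-minute maximum detection range by per-band closed form + plain max."""
    best = -np.inf
    best_b = -1
    for b in usable_bands:
        A = pl_at(pl_table, int(b), depth, 1.0)  # PL law at 1 m is the intercept
        n = pl_at(pl_table, int(b), depth, 1.0) - pl_at(pl_table, int(b), depth, 10.0)
        r = 10.0 ** ((A + sl_row[b] - nl_row[b] - dt) / n)
        if r > best:
            best = r
            best_b = int(b)
    return best, best_b
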
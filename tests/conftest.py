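import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pamrange.bands import AmbientSeries, BandScheme, make_band_scheme
from pamrange.propagation import PLFitTable

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def kw_scheme():
    """The 46-band killer whale pulsed-call scheme."""
    return make_band_scheme(1000, 14800, 300)


@pytest.fixture(scope="session")
def toy_scenario():
    from pamrange.synthetic import gen_site_scenario

    return gen_site_scenario("toy3band", 7)


@pytest.fixture(scope="session")
def toy_pl_table(toy_scenario):
    from pamrange.propagation import fit_pl_loglaw

    return fit_pl_loglaw(
        toy_scenario.pl_samples,
        toy_scenario.scheme,
        depth_bins=np.arange(0.0, 201.0, 40.0),
    )


def make_fit_table(
    scheme: BandScheme,
    A_by_cell: dict,
    n_by_cell: dict,
    centers,
    usable=None,
) -> PLFitTable:
    """Construct a PLFitTable directly from coefficient dicts keyed (band, center)."""
    centers = np.asarray(centers, dtype=float)
    rows = []
    for b in range(scheme.n_bands):
        for c in centers:
            key = (b, float(c))
            ok = True if usable is None else usable.get(key, True)
            rows.append((b, c, A_by_cell[key], n_by_cell[key], 1.0, 0.0, 10, ok))
    table = pd.DataFrame(
        rows,
        columns=[
            "band_index", "depth_bin_center_m", "A_db", "n",
            "r2", "rmse_db", "n_samples", "usable",
        ],
    )
    return PLFitTable(table=table, scheme=scheme, depth_bin_centers=centers)


def constant_noise(scheme: BandScheme, n_minutes: int, level: float) -> AmbientSeries:
    return AmbientSeries(
        timestamps=np.array([f"m{t}" for t in range(n_minutes)]),
        spl=np.full((n_minutes, scheme.n_bands), float(level)),
        scheme=scheme,
    )
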
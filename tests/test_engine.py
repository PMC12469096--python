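"""Monte Carlo detection engine: closed forms, oracle equivalence, invariants."""

import dataclasses

import numpy as np
import pytest

from conftest import constant_noise, make_fit_table
from _oracle import brute_force_curves

from pamrange.bands import AmbientSeries, NoiseStrata, make_band_scheme
from pamrange.depth import DepthModelParams, UniformDepthModel
from pamrange.engine import (
    DetectionConfig,
    Scenario,
    detection_curve,
    detection_range_band,
    max_detection_range,
    median_range_at_probability,
    run_monte_carlo,
    run_sensitivity,
    run_stratified,
    write_ensemble_csvs,
)
from pamrange.source_level import SourceLevelSpec, allocate_band_levels, sample_broadband_sl

BAND1 = make_band_scheme(0, 300, 300)


class TestDetectionRangeBand:
    def test_unit_range_when_terms_cancel(self):
        assert detection_range_band(0.0, 20.0, 105.0, 100.0, 5.0) == pytest.approx(1.0)

    def test_closed_form_value(self):
        assert detection_range_band(0.0, 20.0, 155.0, 100.0, 5.0) == pytest.approx(
            316.228, abs=1e-3
        )

    def test_decade_property_in_noise(self):
        r0 = detection_range_band(-5.0, 15.0, 150.0, 80.0, 5.0)
        r1 = detection_range_band(-5.0, 15.0, 150.0, 95.0, 5.0)  # +n dB noise
        assert r0 / r1 == pytest.approx(10.0, rel=1e-12)

    def test_monotonicities(self):
        base = detection_range_band(-5.0, 15.0, 150.0, 80.0, 5.0)
        assert detection_range_band(-4.0, 15.0, 150.0, 80.0, 5.0) > base
        assert detection_range_band(-5.0, 15.0, 151.0, 80.0, 5.0) > base
        assert detection_range_band(-5.0, 15.0, 150.0, 81.0, 5.0) < base
        assert detection_range_band(-5.0, 15.0, 150.0, 80.0, 6.0) < base

    def test_non_positive_n_errors(self):
        with pytest.raises(ValueError):
            detection_range_band(0.0, 0.0, 150.0, 80.0, 5.0)


class TestMaxDetectionRange:
    def test_direct_max(self):
        assert max_detection_range([100.0, 500.0, 300.0]) == (500.0, 1)

    def test_tie_goes_to_lowest_band(self):
        assert max_detection_range([500.0, 500.0]) == (500.0, 0)

    def test_usable_mask_respected(self):
        r, b = max_detection_range([100.0, 500.0, 300.0], usable=[True, False, True])
        assert (r, b) == (300.0, 2)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            v = rng.uniform(10, 1e4, size=46)
            r, b = max_detection_range(v)
            assert r == v.max()
            assert b == int(np.argmax(v))

    def test_no_usable_band_errors(self):
        with pytest.raises(ValueError):
            max_detection_range([1.0, 2.0], usable=[False, False])


class TestDetectionCurve:
    def test_direct_count(self):
        p = detection_curve([100.0, 200.0, 300.0], [150.0])
        assert p[0] == pytest.approx(2 / 3)

    def test_boundaries(self):
        p = detection_curve([100.0, 200.0, 300.0], [50.0, 1000.0])
        assert p[0] == 1.0 and p[1] == 0.0

    def test_threshold_is_inclusive(self):
        # a minute whose Rmax equals r counts as detected at r
        p = detection_curve([100.0, 200.0], [200.0])
        assert p[0] == pytest.approx(0.5)

    def test_single_minute_indicator(self):
        grid = np.array([10.0, 99.0, 100.0, 101.0])
        np.testing.assert_array_equal(detection_curve([100.0], grid), [1, 1, 1, 0])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            detection_curve([], [100.0])


@pytest.fixture(scope="module")
def toy_ensemble(toy_scenario, toy_pl_table):
    cfg = DetectionConfig(n_sl=20, n_depth=20, seed=42)
    return run_monte_carlo(
        toy_scenario.noise, toy_pl_table, toy_scenario.sl_spec,
        toy_scenario.depth_params, cfg,
    )


class TestMedianRangeInversion:
    def _step_ensemble(self, rmax_values, grid=None):
        """Degenerate one-curve ensemble built from explicit Rmax samples."""
        if grid is None:
            grid = np.logspace(0, 4, 400)
        table = make_fit_table(BAND1, {(0, 10.0): 0.0}, {(0, 10.0): 15.0}, [10.0])
        # not used; we invert detection_curve directly through the helper
        from pamrange.engine import _invert_curve

        curve = detection_curve(rmax_values, grid)
        return grid, curve, _invert_curve

    def test_single_step_curve(self):
        grid, curve, invert = self._step_ensemble([500.0, 500.0, 500.0])
        r, unbounded = invert(grid, curve, 0.5)
        assert not unbounded
        assert r == pytest.approx(500.0, rel=0.03)  # within one log-grid cell

    def test_empirical_survival_inversion(self):
        grid, curve, invert = self._step_ensemble([100.0, 200.0, 300.0])
        r, _ = invert(grid, curve, 0.5)
        # P(r) >= 0.5 exactly up to r = 200 (2 of 3 minutes)
        assert r == pytest.approx(200.0, rel=0.03)

    def test_monotone_in_probability(self, toy_ensemble):
        r01, _ = median_range_at_probability(toy_ensemble, 0.1)
        r05, _ = median_range_at_probability(toy_ensemble, 0.5)
        r09, _ = median_range_at_probability(toy_ensemble, 0.9)
        assert r01 >= r05 >= r09

    def test_curve_starting_below_p_gives_zero(self):
        grid, curve, invert = self._step_ensemble([1e-3])  # below the grid
        r, unbounded = invert(grid, curve, 0.5)
        assert r == 0.0 and not unbounded

    def test_unbounded_flag(self):
        grid, curve, invert = self._step_ensemble([1e9])  # beyond the grid
        r, unbounded = invert(grid, curve, 0.5)
        assert r == grid[-1] and unbounded


class TestRunMonteCarlo:
    def test_default_config_runs_ten_thousand_curves(self, toy_scenario, toy_pl_table):
        ens = run_monte_carlo(
            toy_scenario.noise, toy_pl_table, toy_scenario.sl_spec,
            toy_scenario.depth_params, DetectionConfig(seed=1),
        )
        assert ens.n_realizations == 10_000
        assert ens.curves.shape == (10_000, 200)

    def test_degenerate_ensemble_collapses(self):
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        noise = constant_noise(BAND1, 5, 85.0)
        spec = SourceLevelSpec(150.0, 0.0, 0.0)
        cfg = DetectionConfig(n_sl=1, n_depth=1, seed=0)
        ens = run_monte_carlo(noise, table, spec, DepthModelParams(2.0, 0.77, 200), cfg)
        assert ens.curves.shape[0] == 1
        for k in range(len(ens.percentiles)):
            np.testing.assert_array_equal(ens.percentile_curves[k], ens.curves[0])
        # indicator step at the closed-form range
        r_true = detection_range_band(-5.0, 15.0, 150.0, 85.0, 5.0)
        grid = ens.range_grid
        np.testing.assert_array_equal(ens.curves[0], (grid <= r_true).astype(float))

    def test_single_band_median_matches_closed_form(self):
        # depth-independent PL, constant noise, odd SL pool: the median of
        # per-realization ranges is the closed form at the median drawn SL
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        noise = constant_noise(BAND1, 3, 85.0)
        spec = SourceLevelSpec(150.0, 6.5, 0.0)
        cfg = DetectionConfig(
            n_sl=9, n_depth=1, seed=3, range_grid=np.logspace(0, 6, 2000)
        )
        ens = run_monte_carlo(noise, table, spec, DepthModelParams(2.0, 0.77, 200), cfg)
        ss = np.random.SeedSequence(3)
        child_sl, _ = ss.spawn(2)
        sl_pool = sample_broadband_sl(spec, 9, np.random.default_rng(child_sl))
        r_expected = detection_range_band(-5.0, 15.0, np.median(sl_pool), 85.0, 5.0)
        r_engine, _ = median_range_at_probability(ens, 0.5, which="per_realization")
        assert r_engine == pytest.approx(r_expected, rel=0.01)

    def test_scheme_mismatch_errors(self, toy_scenario, toy_pl_table):
        other = constant_noise(BAND1, 4, 80.0)
        with pytest.raises(ValueError, match="scheme"):
            run_monte_carlo(other, toy_pl_table, toy_scenario.sl_spec,
                            toy_scenario.depth_params, DetectionConfig(n_sl=2, n_depth=2))

    def test_all_bands_unusable_errors(self):
        table = make_fit_table(
            BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0],
            usable={(0, 10.0): False},
        )
        noise = constant_noise(BAND1, 3, 85.0)
        with pytest.warns(UserWarning), pytest.raises(ValueError, match="unusable"):
            run_monte_carlo(noise, table, SourceLevelSpec(150, 1, 0),
                            DepthModelParams(2.0, 0.77, 200),
                            DetectionConfig(n_sl=2, n_depth=2))

    def test_unusable_band_excluded_with_warning(self):
        scheme = make_band_scheme(0, 600, 300)
        centers = [10.0]
        A = {(0, 10.0): -5.0, (1, 10.0): -5.0}
        n = {(0, 10.0): 15.0, (1, 10.0): 15.0}
        table = make_fit_table(scheme, A, n, centers, usable={(1, 10.0): False})
        noise = constant_noise(scheme, 3, 85.0)
        with pytest.warns(UserWarning, match="excluding 1 band"):
            ens = run_monte_carlo(noise, table, SourceLevelSpec(150, 0, -3),
                                  DepthModelParams(2.0, 0.77, 200),
                                  DetectionConfig(n_sl=1, n_depth=1))
        assert ens.argmax_band_share[1] == 0.0

    def test_argmax_concentrates_in_first_band_under_negative_slope(self):
        scheme = make_band_scheme(0, 1500, 300)
        centers = [10.0]
        A = {(b, 10.0): -5.0 for b in range(5)}
        n = {(b, 10.0): 15.0 for b in range(5)}
        table = make_fit_table(scheme, A, n, centers)
        noise = constant_noise(scheme, 4, 85.0)  # flat noise
        ens = run_monte_carlo(noise, table, SourceLevelSpec(150, 3, -2.0),
                              DepthModelParams(2.0, 0.77, 200),
                              DetectionConfig(n_sl=5, n_depth=5, seed=8))
        assert ens.argmax_band_share[0] == pytest.approx(1.0)
        assert ens.argmax_band_share.sum() == pytest.approx(1.0)


class TestOracleEquivalence:
    def _random_instance(self, rng, seed):
        n_bands = int(rng.integers(1, 6))
        scheme = make_band_scheme(1000, 1000 + 300 * n_bands, 300)
        n_minutes = int(rng.integers(1, 21))
        noise = AmbientSeries(
            timestamps=np.array([f"m{t}" for t in range(n_minutes)]),
            spl=rng.uniform(70, 100, size=(n_minutes, n_bands)),
            scheme=scheme,
        )
        centers = [10.0, 50.0] if rng.random() < 0.5 else [30.0]
        A = {(b, c): rng.uniform(-15, 5) for b in range(n_bands) for c in centers}
        n = {(b, c): rng.uniform(10, 20) for b in range(n_bands) for c in centers}
        table = make_fit_table(scheme, A, n, centers)
        spec = SourceLevelSpec(rng.uniform(140, 160), rng.uniform(0, 8),
                               rng.uniform(-1.0, 0.5))
        depth_model = DepthModelParams(2.0, 0.77, 200.0)
        cfg = DetectionConfig(
            n_sl=int(rng.integers(1, 4)), n_depth=int(rng.integers(1, 4)),
            seed=seed, range_grid=np.logspace(1, 5, 20),
        )
        return noise, table, spec, depth_model, cfg

    def _oracle_inputs(self, spec, depth_model, cfg, scheme):
        """Re-derive the engine's seeded pools, then hand them to the oracle."""
        ss = np.random.SeedSequence(cfg.seed)
        child_sl, child_depth = ss.spawn(2)
        sl_pool = sample_broadband_sl(spec, cfg.n_sl, np.random.default_rng(child_sl))
        depth_pool = depth_model.sample(cfg.n_depth, np.random.default_rng(child_depth))
        sl_real = np.repeat(sl_pool, cfg.n_depth)
        depths = np.tile(depth_pool, cfg.n_sl)
        sl_bands = allocate_band_levels(sl_real, spec.slope, scheme)
        return sl_bands, depths

    @pytest.mark.parametrize("trial", range(10))
    def test_engine_equals_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        noise, table, spec, depth_model, cfg = self._random_instance(rng, seed=trial)
        ens = run_monte_carlo(noise, table, spec, depth_model, cfg)
        sl_bands, depths = self._oracle_inputs(spec, depth_model, cfg, noise.scheme)
        expected = brute_force_curves(
            noise.spl, table, sl_bands, depths,
            usable_bands=table.usable_bands(), dt=cfg.dt, grid=cfg.range_grid,
        )
        np.testing.assert_allclose(ens.curves, expected, atol=1e-9)


class TestInvariants:
    def test_curves_non_increasing_and_bounded(self, toy_ensemble):
        assert np.all(toy_ensemble.curves >= 0.0)
        assert np.all(toy_ensemble.curves <= 1.0)
        assert np.all(np.diff(toy_ensemble.curves, axis=1) <= 1e-12)

    def test_percentile_curves_pointwise_ordered(self, toy_ensemble):
        pc = toy_ensemble.percentile_curves
        assert np.all(pc[0] <= pc[1] + 1e-12)
        assert np.all(pc[1] <= pc[2] + 1e-12)

    def test_argmax_histogram_sums_to_one(self, toy_ensemble):
        assert toy_ensemble.argmax_band_share.sum() == pytest.approx(1.0)

    def test_seed_determinism_bit_identical_csvs(self, tmp_path, toy_scenario, toy_pl_table):
        cfg = DetectionConfig(n_sl=10, n_depth=10, seed=99)
        files = []
        for d in ("a", "b"):
            ens = run_monte_carlo(
                toy_scenario.noise, toy_pl_table, toy_scenario.sl_spec,
                toy_scenario.depth_params, cfg,
            )
            paths = write_ensemble_csvs(ens, tmp_path / d)
            files.append(paths)
        for key in files[0]:
            assert files[0][key].read_bytes() == files[1][key].read_bytes()


class TestStratifiedRuns:
    def _strata(self, n):
        k = n // 2
        return NoiseStrata(
            thresholds=(0.0, 0.0),
            members={"low": np.arange(k), "high": np.arange(k, n)},
        )

    def test_identical_noise_gives_identical_ensembles(self):
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        noise = constant_noise(BAND1, 8, 85.0)
        ens = run_stratified(
            noise, self._strata(8), table, SourceLevelSpec(150, 5, 0),
            DepthModelParams(2.0, 0.77, 200), DetectionConfig(n_sl=4, n_depth=4, seed=5),
        )
        np.testing.assert_array_equal(ens["low"].curves, ens["high"].curves)

    def test_noisier_stratum_never_longer(self):
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        rng = np.random.default_rng(2)
        spl = np.concatenate([80 + rng.random(10), 90 + rng.random(10)])[:, None]
        noise = AmbientSeries(
            timestamps=np.array([f"m{t}" for t in range(20)]), spl=spl, scheme=BAND1
        )
        ens = run_stratified(
            noise, self._strata(20), table, SourceLevelSpec(150, 5, 0),
            DepthModelParams(2.0, 0.77, 200), DetectionConfig(n_sl=4, n_depth=4, seed=5),
        )
        r_low, _ = median_range_at_probability(ens["low"], 0.5)
        r_high, _ = median_range_at_probability(ens["high"], 0.5)
        assert r_high <= r_low

    def test_exact_decade_shift_between_strata(self):
        # single band, n = 15: strata offset by exactly 15 dB differ in median
        # range by exactly a factor 10 (grid chosen so a decade is a whole
        # number of cells)
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        spl = np.concatenate([np.full(5, 80.0), np.full(5, 95.0)])[:, None]
        noise = AmbientSeries(
            timestamps=np.array([f"m{t}" for t in range(10)]), spl=spl, scheme=BAND1
        )
        cfg = DetectionConfig(
            n_sl=4, n_depth=4, seed=5, range_grid=np.logspace(0, 6, 301)
        )
        ens = run_stratified(noise, self._strata(10), table,
                             SourceLevelSpec(150, 5, 0),
                             DepthModelParams(2.0, 0.77, 200), cfg)
        r_low, _ = median_range_at_probability(ens["low"], 0.5)
        r_high, _ = median_range_at_probability(ens["high"], 0.5)
        assert r_low / r_high == pytest.approx(10.0, rel=1e-9)

    def test_empty_stratum_errors(self):
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        noise = constant_noise(BAND1, 4, 85.0)
        strata = NoiseStrata(thresholds=(0, 0),
                             members={"low": np.arange(4), "high": np.array([], int)})
        with pytest.raises(ValueError, match="empty"):
            run_stratified(noise, strata, table, SourceLevelSpec(150, 5, 0),
                           DepthModelParams(2.0, 0.77, 200),
                           DetectionConfig(n_sl=2, n_depth=2))


class TestSensitivity:
    def _base(self):
        table = make_fit_table(BAND1, {(0, 10.0): -5.0}, {(0, 10.0): 15.0}, [10.0])
        noise = constant_noise(BAND1, 6, 85.0)
        return Scenario(
            noise=noise, pl=table, sl_spec=SourceLevelSpec(150, 5, 0),
            depth_model=DepthModelParams(2.0, 0.77, 200),
            config=DetectionConfig(n_sl=4, n_depth=4, seed=6),
        )

    def test_null_swap_difference_is_exactly_zero(self):
        base = self._base()
        results = run_sensitivity(base, [{"source_level": base.sl_spec}])
        assert results[0].difference == 0.0

    def test_two_factor_swap_rejected(self):
        base = self._base()
        with pytest.raises(ValueError, match="exactly one factor"):
            run_sensitivity(base, [{"source_level": base.sl_spec, "noise": base.noise}])

    def test_unknown_factor_rejected(self):
        base = self._base()
        with pytest.raises(ValueError, match="unknown factor"):
            run_sensitivity(base, [{"bathymetry": None}])

    def test_flat_slope_helps_when_low_band_is_masked(self):
        # low-frequency-heavy noise: tilting energy into the noisy low band
        # shortens the range, so the flat-spectrum variant detects farther
        scheme = make_band_scheme(0, 900, 300)
        centers = [10.0]
        A = {(b, 10.0): -5.0 for b in range(3)}
        n = {(b, 10.0): 15.0 for b in range(3)}
        table = make_fit_table(scheme, A, n, centers)
        spl = np.tile(np.array([100.0, 80.0, 80.0]), (6, 1))
        noise = AmbientSeries(
            timestamps=np.array([f"m{t}" for t in range(6)]), spl=spl, scheme=scheme
        )
        base = Scenario(
            noise=noise, pl=table, sl_spec=SourceLevelSpec(150, 3, -2.0),
            depth_model=DepthModelParams(2.0, 0.77, 200),
            config=DetectionConfig(n_sl=4, n_depth=4, seed=6),
        )
        flat = dataclasses.replace(base.sl_spec, slope=0.0)
        results = run_sensitivity(base, [{"source_level": flat}])
        assert results[0].difference > 0.0

    def test_depth_swap_follows_pl_depth_gradient(self):
        # intercept A grows with depth -> deeper callers detected farther;
        # the uniform depth model puts far more mass at depth than the
        # log-logistic (median ~7.5 m), so swapping to it lengthens the range
        centers = [10.0, 190.0]
        A = {(0, 10.0): -15.0, (0, 190.0): 5.0}
        n = {(0, 10.0): 15.0, (0, 190.0): 15.0}
        table = make_fit_table(BAND1, A, n, centers)
        base = Scenario(
            noise=constant_noise(BAND1, 6, 85.0), pl=table,
            sl_spec=SourceLevelSpec(150, 5, 0),
            depth_model=DepthModelParams(2.0212, 0.7739, 200),
            config=DetectionConfig(n_sl=6, n_depth=6, seed=6),
        )
        results = run_sensitivity(base, [{"depth": UniformDepthModel(z_max=200.0)}])
        assert results[0].difference > 0.0
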
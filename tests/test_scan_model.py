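"""Motor-unit pool generation and CMAP scan simulation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from cmapscan import (
    HEALTHY_GROUP,
    SCI_GROUP,
    DistributionSpec,
    MotorUnit,
    MotorUnitPool,
    PoolSpec,
    ScanProtocol,
    activation_probability,
    generate_cohort,
    generate_pool,
    prescan_search,
    simulate_scan,
)
from cmapscan.scan_model import expected_scan_amplitude, s50_intensity


def make_spec(n_units=10, amp=("point", {"value": 1.0}), thr=("uniform", {"low": 5.0, "high": 15.0}),
              **kw):
    return PoolSpec(n_units=n_units, amplitude=DistributionSpec(*amp),
                    threshold=DistributionSpec(*thr), **kw)


class TestGeneratePool:
    def test_single_unit_point_mass(self):
        pool = generate_pool(make_spec(n_units=1, amp=("point", {"value": 10.0})), seed=0)
        assert pool.n_units == 1
        assert pool.max_expected_cmap == pytest.approx(10.0)

    def test_healthy_like_pool_hits_target_cmap(self):
        spec = make_spec(n_units=108, amp=("lognormal", {"mean": 0.155, "sigma": 0.5}),
                         thr=("uniform", {"low": 4.5, "high": 16.0}),
                         target_max_cmap=16.75)
        pool = generate_pool(spec, seed=3)
        assert pool.n_units == 108
        assert pool.max_expected_cmap == pytest.approx(16.75)

    def test_sci_like_pool_with_reinnervation(self):
        spec = make_spec(n_units=59, amp=("lognormal", {"mean": 0.136, "sigma": 0.5}),
                         thr=("uniform", {"low": 8.5, "high": 19.4}),
                         reinnervation_factor=1.5, target_max_cmap=8.01)
        pool = generate_pool(spec, seed=3)
        assert pool.n_units == 59
        assert pool.max_expected_cmap == pytest.approx(8.01)

    def test_reinnervation_scales_amplitudes(self):
        base = generate_pool(make_spec(), seed=5)
        scaled = generate_pool(make_spec(reinnervation_factor=2.0), seed=5)
        np.testing.assert_allclose(scaled.amplitudes, 2.0 * base.amplitudes)

    def test_determinism(self):
        spec = make_spec(amp=("lognormal", {"mean": 0.2, "sigma": 0.5}))
        p1, p2 = generate_pool(spec, seed=11), generate_pool(spec, seed=11)
        np.testing.assert_array_equal(p1.amplitudes, p2.amplitudes)
        np.testing.assert_array_equal(p1.thresholds, p2.thresholds)

    @pytest.mark.parametrize(
        "bad",
        [
            ("lognormal", {"mean": -1.0, "sigma": 0.5}),
            ("normal", {"mean": 0.2, "sd": -0.1}),
            ("uniform", {"low": -2.0, "high": 1.0}),
            ("point", {"value": 0.0}),
        ],
    )
    def test_invalid_distribution_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            DistributionSpec(*bad)


class TestActivationProbability:
    def test_half_at_threshold_mean(self):
        unit = MotorUnit(1.0, 10.0, 0.05)
        assert activation_probability(unit, 10.0) == pytest.approx(0.5)

    def test_zero_far_below_threshold(self):
        unit = MotorUnit(1.0, 10.0, 0.02)
        assert activation_probability(unit, 0.0) < 1e-12

    def test_one_sd_above_matches_numerical_gaussian_integral(self):
        unit = MotorUnit(1.0, 10.0, 0.05)
        # independent oracle: numerically integrate the Gaussian density
        sd = unit.threshold_sd
        pdf = lambda x: np.exp(-0.5 * ((x - 10.0) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        expected, _ = quad(pdf, -np.inf, 10.0 + sd)
        assert activation_probability(unit, 10.0 + sd) == pytest.approx(expected, abs=1e-9)

    def test_nondecreasing_in_intensity(self):
        unit = MotorUnit(1.0, 10.0, 0.05)
        grid = activation_probability(unit, np.linspace(0, 20, 200))
        assert np.all(np.diff(grid) >= 0)


class TestSimulateScan:
    def test_saturation_above_all_thresholds(self):
        pool = generate_pool(make_spec(n_units=5, noise_sd=0.0), seed=1)
        hi = pool.thresholds.max() * 1.5
        protocol = ScanProtocol(hi + 1.0, hi, n_stimuli=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = simulate_scan(pool, protocol, seed=2)
        np.testing.assert_allclose(scan.amplitude, pool.max_expected_cmap)

    def test_silence_below_all_thresholds(self):
        pool = generate_pool(make_spec(n_units=5, noise_sd=0.0), seed=1)
        protocol = ScanProtocol(1.0, 0.5, n_stimuli=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = simulate_scan(pool, protocol, seed=2)
        np.testing.assert_allclose(scan.amplitude, 0.0)

    def test_firing_fraction_at_threshold_matches_binomial(self):
        unit = MotorUnit(1.0, 10.0, 0.05)
        pool = MotorUnitPool((unit,), noise_sd=0.0)
        n = 10_000
        protocol = ScanProtocol(10.0 + 1e-9, 10.0 - 1e-9, n_stimuli=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scan = simulate_scan(pool, protocol, seed=9)
        frac = (scan.amplitude > 0.5).mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_expected_curve_nondecreasing(self):
        pool = generate_pool(make_spec(n_units=20,
                                       amp=("lognormal", {"mean": 0.2, "sigma": 0.5})), seed=4)
        curve = expected_scan_amplitude(pool, np.linspace(0, 25, 300))
        assert np.all(np.diff(curve) >= -1e-12)

    def test_amplitude_bounded_by_pool_sum_plus_noise(self):
        pool = generate_pool(make_spec(n_units=10, noise_sd=0.1), seed=6)
        protocol = ScanProtocol.from_prescan(pool, n_stimuli=300)
        scan = simulate_scan(pool, protocol, seed=7)
        assert scan.amplitude.max() <= pool.max_expected_cmap + 5 * 0.1

    def test_determinism(self):
        pool = generate_pool(make_spec(noise_sd=0.05), seed=1)
        protocol = ScanProtocol.from_prescan(pool)
        s1 = simulate_scan(pool, protocol, seed=42)
        s2 = simulate_scan(pool, protocol, seed=42)
        np.testing.assert_array_equal(s1.amplitude, s2.amplitude)

    def test_out_of_range_protocol_warns(self):
        pool = generate_pool(make_spec(n_units=3), seed=1)
        with pytest.warns(UserWarning, match="recruitment range"):
            simulate_scan(pool, ScanProtocol(2.0, 1.0, n_stimuli=10), seed=0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_simulated_amplitudes_stay_in_bounds(self, seed):
        pool = generate_pool(make_spec(n_units=6, noise_sd=0.02), seed=seed)
        protocol = ScanProtocol.from_prescan(pool, n_stimuli=100)
        scan = simulate_scan(pool, protocol, seed=seed + 1)
        assert scan.amplitude.min() >= 0
        assert scan.amplitude.max() <= pool.max_expected_cmap + 5 * 0.02


class TestPrescanSearch:
    def test_degenerate_single_unit(self):
        pool = MotorUnitPool((MotorUnit(1.0, 10.0, 0.001),))
        s0, s100 = prescan_search(pool, tolerance=0.05)
        assert s0 == pytest.approx(10.0, abs=0.2)
        assert s100 == pytest.approx(10.0, abs=0.2)
        assert s0 < s100

    def test_two_unit_ordering(self):
        pool = MotorUnitPool((MotorUnit(1.0, 5.0, 0.01), MotorUnit(1.0, 15.0, 0.01)))
        s0, s100 = prescan_search(pool, tolerance=0.05)
        assert s0 == pytest.approx(5.0, abs=0.5)
        assert s100 == pytest.approx(15.0, abs=0.5)

    def test_matches_dense_grid_search(self, rng):
        pool = generate_pool(make_spec(n_units=8,
                                       amp=("lognormal", {"mean": 0.3, "sigma": 0.4})), seed=13)
        tol = 0.05
        s0, s100 = prescan_search(pool, tolerance=tol)
        grid = np.linspace(0.0, 25.0, 20_001)
        mus, sds = pool.thresholds, pool.threshold_sds
        from scipy.special import ndtr
        p = ndtr((grid[:, None] - mus) / sds)
        g0 = grid[np.argmax(p.max(axis=1) >= 0.05)]
        g100 = grid[np.argmax(p.min(axis=1) >= 0.95)]
        assert abs(s0 - g0) <= tol
        assert abs(s100 - g100) <= tol

    def test_s50_is_half_recruitment_point(self):
        pool = MotorUnitPool((MotorUnit(2.0, 10.0, 0.05),))
        # a single unit reaches half its expected amplitude at its mean threshold
        assert s50_intensity(pool) == pytest.approx(10.0, abs=0.05)


class TestGenerateCohort:
    def test_shapes_and_determinism(self):
        t1, scans1 = generate_cohort(n_per_group=3, seed=5, n_stimuli=120)
        t2, _ = generate_cohort(n_per_group=3, seed=5, n_stimuli=120)
        assert len(t1) == 6
        assert len(scans1) == 6
        assert set(t1.df["group"]) == {"SCI", "control"}
        assert t1.df.equals(t2.df)

    def test_group_cmap_means_near_generative_targets(self):
        # resampling check: cohort group means should sit near the configured
        # generative means within sampling error of the truncated normals
        tables = [generate_cohort(n_per_group=13, seed=s, n_stimuli=150)[0]
                  for s in range(6)]
        sci = np.concatenate([t.column("cmap_mV", "SCI") for t in tables])
        ctl = np.concatenate([t.column("cmap_mV", "control") for t in tables])
        assert abs(sci.mean() - SCI_GROUP.cmap_mean) < 3 * SCI_GROUP.cmap_sd / np.sqrt(len(sci)) + 0.3
        assert abs(ctl.mean() - HEALTHY_GROUP.cmap_mean) < 3 * HEALTHY_GROUP.cmap_sd / np.sqrt(len(ctl)) + 0.3

    def test_clinical_covariates_only_for_sci(self):
        table, _ = generate_cohort(n_per_group=2, seed=1, n_stimuli=100)
        sci = table.df[table.df["group"] == "SCI"]
        ctl = table.df[table.df["group"] == "control"]
        assert sci["grassp"].notna().all()
        assert "grassp" not in ctl or ctl["grassp"].isna().all()
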
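"""Circular/axial statistics against brute-force and library oracles."""

import math

import numpy as np
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats

from skytuner import (
    NoPreferredAngleError,
    UndefinedStatisticError,
    axial_double,
    axial_halve,
    ci95_mean_direction,
    circ_sd_from_r,
    circular_distance,
    linear_circular_corr,
    phi_max,
    rayleigh_test,
    resultant,
)


def brute_force_resultant(angles_deg, weights=None):
    """Independent oracle: explicit x/y unit-vector summation."""
    w = np.ones(len(angles_deg)) if weights is None else np.asarray(weights)
    x = sum(wi * math.cos(math.radians(a)) for a, wi in zip(angles_deg, w))
    y = sum(wi * math.sin(math.radians(a)) for a, wi in zip(angles_deg, w))
    r = math.hypot(x, y) / sum(w)
    mean = math.degrees(math.atan2(y, x)) % 360.0
    return mean, r


class TestResultant:
    def test_identical_angles_give_unit_vector(self):
        assert resultant([45.0] * 7) == pytest.approx((45.0, 1.0))

    def test_two_orthogonal_vectors(self):
        mean, r = resultant([0.0, 90.0])
        assert mean == pytest.approx(45.0)
        assert r == pytest.approx(math.sqrt(2) / 2)

    def test_full_cancellation(self):
        mean, r = resultant([0.0, 90.0, 180.0, 270.0])
        assert r == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(mean)

    def test_empty_input_raises(self):
        with pytest.raises(UndefinedStatisticError):
            resultant([])

    def test_zero_weights_raise(self):
        with pytest.raises(UndefinedStatisticError):
            resultant([10.0, 20.0], [0.0, 0.0])

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 51)
            a = rng.uniform(0, 360, n)
            w = rng.uniform(0.1, 3.0, n) if rng.random() < 0.5 else None
            mean, r = resultant(a, w)
            mean_o, r_o = brute_force_resultant(a, w)
            assert r == pytest.approx(r_o, abs=1e-9)
            if r > 1e-9:
                assert circular_distance(mean, mean_o) < 1e-9

    @given(
        st_.lists(st_.floats(0, 359.999), min_size=2, max_size=30),
        st_.floats(-720, 720),
    )
    @settings(max_examples=200, deadline=None)
    def test_r_invariant_under_global_rotation(self, angles, shift):
        _, r0 = resultant(angles)
        _, r1 = resultant([(a + shift) % 360 for a in angles])
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestAxialTransforms:
    def test_axial_pair_collapses_when_doubled(self):
        assert axial_double([10.0, 190.0]) == pytest.approx([20.0, 20.0])

    def test_halve_maps_into_axial_range(self):
        assert axial_halve(240.0) == pytest.approx(120.0)

    def test_round_trip_recovers_axial_class(self):
        assert phi_max([80.0, 260.0], periodicity=180) == pytest.approx(80.0)


class TestPhiMax:
    def test_axial_identity(self):
        assert phi_max([10.0, 190.0, 10.0, 190.0], 180) == pytest.approx(10.0)

    def test_degenerate_axial_pair_raises(self):
        with pytest.raises(NoPreferredAngleError):
            phi_max([0.0, 90.0], periodicity=180)

    def test_recovers_true_axis_from_cosine_modulated_sample(self, rng):
        # inverse-CDF draw from density ∝ max(0, 1 + 2·cos(2(φ−Φ))), Φ=51.8°
        true = 51.8
        cand = rng.uniform(0, 360, 40000)
        dens = np.maximum(
            0.0, 1.0 + 2.0 * np.cos(np.deg2rad(2 * (cand - true)))
        )
        keep = rng.uniform(0, 3.0, cand.size) < dens
        sample = cand[keep][:1000]
        assert circular_distance(
            phi_max(sample, 180), true, 180
        ) < 3.0

    @given(
        st_.lists(st_.floats(0, 359.99), min_size=3, max_size=20),
        st_.floats(0, 360),
    )
    @settings(max_examples=200, deadline=None)
    def test_rotation_equivariance(self, angles, c):
        try:
            p0 = phi_max(angles, 360)
        except UndefinedStatisticError:
            return
        p1 = phi_max([(a + c) % 360 for a in angles], 360)
        assert circular_distance(p1, (p0 + c) % 360) < 1e-6

    @given(
        st_.lists(st_.floats(0, 179.99), min_size=3, max_size=15),
        st_.lists(st_.booleans(), min_size=15, max_size=15),
    )
    @settings(max_examples=200, deadline=None)
    def test_axial_estimate_invariant_under_180_flips(self, angles, flips):
        flipped = [
            (a + 180.0) % 360 if f else a for a, f in zip(angles, flips)
        ]
        try:
            p0 = phi_max(angles, 180)
        except UndefinedStatisticError:
            return
        assert circular_distance(phi_max(flipped, 180), p0, 180) < 1e-6


class TestCircSD:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (1.0, 0.0),
            (0.0, math.degrees(math.sqrt(2))),  # ≈ 81.03°
            (0.5, 57.29577951308232),  # (180/π)·√(2·0.5) = 180/π
        ],
    )
    def test_mean_angular_deviation_closed_form(self, r, expected):
        assert circ_sd_from_r(r) == pytest.approx(expected, abs=1e-9)

    def test_unbounded_convention(self):
        assert circ_sd_from_r(1.0, "circular_sd") == 0.0
        assert circ_sd_from_r(0.5, "circular_sd") == pytest.approx(
            math.degrees(math.sqrt(-2 * math.log(0.5)))
        )

    def test_monotone_decreasing_in_r(self):
        rs = np.linspace(0, 1, 50)
        sds = [circ_sd_from_r(r) for r in rs]
        assert all(a > b for a, b in zip(sds, sds[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            circ_sd_from_r(1.2)


class TestCI95:
    def test_arc_vanishes_at_full_concentration(self):
        assert ci95_mean_direction(10, 0.999999) == pytest.approx(0.0, abs=0.1)

    def test_undefined_for_dispersed_sample(self):
        assert ci95_mean_direction(20, 0.2) is None

    def test_axial_arc_is_halved(self):
        full = ci95_mean_direction(100, 0.8, 360)
        axial = ci95_mean_direction(100, 0.8, 180)
        assert axial == pytest.approx(full / 2)

    def test_n_too_small_raises(self):
        with pytest.raises(UndefinedStatisticError):
            ci95_mean_direction(1, 0.9)

    def test_agrees_with_bootstrap_oracle(self, rng):
        # von Mises κ≈2.87 gives r≈0.8; analytic arc vs resampling arc
        a = np.rad2deg(rng.vonmises(0.0, 2.87, 100)) % 360
        mean, r = resultant(a)
        d = ci95_mean_direction(100, r, 360)
        devs = []
        for _ in range(2000):
            m, _ = resultant(rng.choice(a, size=100, replace=True))
            devs.append(abs((m - mean + 180) % 360 - 180))
        assert d == pytest.approx(np.quantile(devs, 0.95), abs=2.0)


class TestLinearCircularCorr:
    def test_noiseless_cosine_gives_r2_one_and_chi2_tail_p(self):
        centers = np.arange(7.5, 360, 15)  # 24 bins
        x = 5.0 + 3.0 * np.cos(np.deg2rad(centers - 40.0))
        r2, p = linear_circular_corr(x, centers, 360)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(math.exp(-12.0), rel=1e-6)

    def test_axial_doubling_detects_180_periodic_signal(self):
        centers = np.arange(7.5, 360, 15)
        x = 5.0 + 3.0 * np.cos(np.deg2rad(2 * (centers - 40.0)))
        r2_ax, p_ax = linear_circular_corr(x, centers, 180)
        assert r2_ax == pytest.approx(1.0, abs=1e-9)
        assert p_ax < 1e-4

    def test_constant_values_raise(self):
        with pytest.raises(UndefinedStatisticError):
            linear_circular_corr([3.0] * 10, np.arange(0, 360, 36))

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            linear_circular_corr([1, 2, 3], [0, 90, 180])

    def test_matches_pingouin_cross_check(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 40))
            a = rng.uniform(0, 360, n)
            x = rng.normal(10, 2, n) + 3 * np.cos(np.deg2rad(a))
            r2, p = linear_circular_corr(x, a, 360)
            r_pg, p_pg = pingouin.circ_corrcl(np.deg2rad(a), x)
            assert r2 == pytest.approx(r_pg**2, abs=1e-9)
            assert p == pytest.approx(p_pg, rel=1e-6, abs=1e-12)

    def test_r2_decreases_with_noise_in_expectation(self, rng):
        centers = np.arange(7.5, 360, 15)
        signal = 10 + 5 * np.cos(np.deg2rad(centers - 60))
        mean_r2 = []
        for sd in (0.5, 2.0, 8.0):
            vals = [
                linear_circular_corr(
                    signal + rng.normal(0, sd, 24), centers
                )[0]
                for _ in range(200)
            ]
            mean_r2.append(np.mean(vals))
        assert mean_r2[0] > mean_r2[1] > mean_r2[2]


class TestRayleigh:
    def test_uniform_sample_rarely_rejects(self, rng):
        high_p = sum(
            rayleigh_test(rng.uniform(0, 360, 500))[1] > 0.05
            for _ in range(100)
        )
        assert high_p >= 94

    def test_identical_angles_reject_strongly(self):
        z, p = rayleigh_test([37.0] * 20)
        assert z == pytest.approx(20.0)
        assert p < 1e-6

    def test_n_below_five_raises(self):
        with pytest.raises(ValueError):
            rayleigh_test([0, 90, 180, 270])

    def test_matches_pingouin_cross_check(self, rng):
        # moderate concentration: the two standard tail approximations
        # agree closely here (they diverge only at astronomically small p)
        a = rng.vonmises(1.0, 0.25, 60)
        z, p = rayleigh_test(np.rad2deg(a) % 360)
        z_pg, p_pg = pingouin.circ_rayleigh(a)
        assert z == pytest.approx(z_pg, rel=1e-9)
        assert p == pytest.approx(p_pg, rel=1e-3)


class TestCircularDistance:
    @pytest.mark.parametrize(
        "a,b,per,expected",
        [
            (107.8, 154.4, 180, 46.6),
            (5.0, 175.0, 180, 10.0),  # wraps through the 0/180 join
            (10.0, 350.0, 360, 20.0),
            (90.0, 90.0, 180, 0.0),
        ],
    )
    def test_smallest_arc(self, a, b, per, expected):
        assert circular_distance(a, b, per) == pytest.approx(expected)
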
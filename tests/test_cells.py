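"""LN model cells: Gabor dimensions, gain functions, calibration, spiking."""

import numpy as np
import pytest
from scipy.special import ndtr

import midfield as mf
from midfield import cells as mc
from midfield.cells import GaborFilterSpec, LNCellSpec


class TestGaborDimension:
    def test_unit_norm(self):
        spec = GaborFilterSpec(center=(7.5, 7.5), orientation=0.3,
                               spatial_frequency=0.15, phase=0.0, envelope_sd=3.0)
        v = mc.make_gabor_dimension(spec, 16, 16, 3)
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_pair_near_orthogonal(self):
        dims = mc.quadrature_pair(16, 16, 3)
        assert abs(float(dims[0] @ dims[1])) < 0.1

    def test_temporal_separability(self):
        spec = GaborFilterSpec(center=(3.5, 3.5), orientation=0.0,
                               spatial_frequency=0.25, phase=0.0, envelope_sd=2.0,
                               temporal_weights=(0.0, 0.0, 1.0))
        v = mc.make_gabor_dimension(spec, 8, 8, 3).reshape(3, 8, 8)
        assert np.all(v[0] == 0.0)
        assert np.all(v[1] == 0.0)

    def test_degenerate_rejected(self):
        spec = GaborFilterSpec(center=(100.0, 100.0), orientation=0.0,
                               spatial_frequency=0.25, phase=np.pi / 2,
                               envelope_sd=0.1)
        with pytest.raises(ValueError):
            mc.make_gabor_dimension(spec, 8, 8, 3)


class TestExpectedRate:
    def test_divisive_without_suppression_is_energy(self):
        cell = mc.make_divisive_cell(8, 8, 2, gamma=2.0, suppression=0.0)
        P = np.random.default_rng(0).standard_normal((50, 3))
        r = mc.expected_rate(cell, P)
        np.testing.assert_allclose(r, 2.0 * (P[:, 0] ** 2 + P[:, 1] ** 2), rtol=1e-12)

    def test_quadratic_zero_at_origin(self):
        cell = mc.make_quadratic_cell(8, 8, 2, gamma=1.5)
        assert mc.expected_rate(cell, np.array([[0.0]]))[0] == 0.0

    def test_or_threshold_noiseless_limits(self):
        dims = mc.quadrature_pair(8, 8, 2)
        cell = LNCellSpec(dimensions=dims, gain_family="or_threshold",
                          theta=1.0, sigma=1e-6)
        p = mc.expected_rate(cell, np.array([[2.0, 0.0], [0.5, -0.4], [0.0, -3.0]]))
        np.testing.assert_allclose(p, [1.0, 0.0, 1.0], atol=1e-9)

    def test_or_probability_at_threshold_vs_monte_carlo(self):
        """At (s1, s2) = (theta, 0) the closed form matches brute-force noise
        averaging and is at least 1/2."""
        theta, sigma = 1.3, 0.6
        dims = mc.quadrature_pair(8, 8, 2)
        cell = LNCellSpec(dimensions=dims, gain_family="or_threshold",
                          theta=theta, sigma=sigma)
        p = mc.expected_rate(cell, np.array([[theta, 0.0]]))[0]
        rng = np.random.default_rng(11)
        n1 = rng.normal(0, sigma, 400000)
        n2 = rng.normal(0, sigma, 400000)
        mc_p = np.mean((np.abs(theta + n1) > theta) | (np.abs(0.0 + n2) > theta))
        assert p == pytest.approx(mc_p, abs=3e-3)
        assert p >= 0.5

    def test_sign_flip_symmetry(self):
        """Gain functions are invariant under sign flip of any projection."""
        rng = np.random.default_rng(2)
        P = rng.standard_normal((40, 3))
        div = mc.make_divisive_cell(8, 8, 2, gamma=1.0, suppression=0.8)
        for col in range(3):
            Q = P.copy(); Q[:, col] *= -1
            np.testing.assert_allclose(mc.expected_rate(div, P), mc.expected_rate(div, Q))
        orc = mc.make_or_cell(8, 8, 2)
        for col in range(2):
            Q = P[:, :2].copy(); Q[:, col] *= -1
            np.testing.assert_allclose(mc.expected_rate(orc, P[:, :2]),
                                       mc.expected_rate(orc, Q))

    def test_arity_mismatch_rejected(self):
        cell = mc.make_quadratic_cell(8, 8, 2)
        with pytest.raises(ValueError):
            mc.expected_rate(cell, np.zeros((5, 2)))


class TestCalibration:
    @pytest.fixture(scope="class")
    def ensemble(self):
        stim = mf.generate_white_noise(6000, 8, 8, seed=8)
        return mf.embed_spatiotemporal(stim, 2).matrix

    def test_divisive_targets_hit(self, ensemble):
        cell = mc.calibrate_gain(mc.make_divisive_cell(8, 8, 2), ensemble)
        proj = ensemble @ cell.dimensions.T
        supp = np.mean(1.0 + cell.suppression * proj[:, 2] ** 2)
        assert supp == pytest.approx(4.26, abs=1e-6)
        assert np.mean(mc.expected_rate(cell, proj)) == pytest.approx(0.56, abs=1e-6)

    def test_unit_variance_closed_form(self):
        """With exactly unit-variance suppressive projections, omega = 3.26."""
        rng = np.random.default_rng(3)
        cell = LNCellSpec(dimensions=np.eye(6)[:3], gain_family="divisive",
                          gamma=1.0, suppression=0.5)
        X = rng.standard_normal((20000, 6))
        X /= np.sqrt((X**2).mean(axis=0))  # unit mean-square projections
        cal = mc.calibrate_gain(cell, X)
        assert cal.suppression == pytest.approx(3.26, rel=1e-9)

    def test_or_threshold_bisection(self, ensemble):
        cell = mc.calibrate_gain(mc.make_or_cell(8, 8, 2), ensemble,
                                 target_mean_rate=0.2)
        proj = ensemble @ cell.dimensions.T
        assert np.mean(mc.expected_rate(cell, proj)) == pytest.approx(0.2, abs=1e-9)

    def test_calibration_idempotent(self, ensemble):
        c1 = mc.calibrate_gain(mc.make_divisive_cell(8, 8, 2), ensemble)
        c2 = mc.calibrate_gain(c1, ensemble)
        assert abs(c1.gamma - c2.gamma) < 1e-9
        assert abs(c1.suppression - c2.suppression) < 1e-9

    def test_unattainable_target_rejected(self, ensemble):
        with pytest.raises(ValueError):
            mc.calibrate_gain(mc.make_or_cell(8, 8, 2), ensemble, target_mean_rate=-0.1)


class TestSimulateSpikes:
    def test_zero_rates_zero_counts(self):
        assert mc.simulate_spikes(np.zeros(100), seed=0).sum() == 0

    def test_poisson_mean_and_fano(self):
        rates = np.full(50000, 0.56)
        y = mc.simulate_spikes(rates, seed=1)
        assert abs(y.mean() - 0.56) < 3 * np.sqrt(0.56 / 50000)
        assert 0.95 < y.var() / y.mean() < 1.05

    def test_determinism(self):
        rates = np.linspace(0, 1, 500)
        a = mc.simulate_spikes(rates, seed=7)
        b = mc.simulate_spikes(rates, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            mc.simulate_spikes(np.array([-0.1]), seed=0)

    def test_bernoulli_bounded(self):
        y = mc.simulate_spikes(np.full(1000, 0.3), seed=2, family="or_threshold")
        assert set(np.unique(y)) <= {0, 1}


def test_cell_json_roundtrip(tmp_path):
    cell = mc.calibrate_gain(
        mc.make_divisive_cell(8, 8, 2),
        mf.embed_spatiotemporal(mf.generate_white_noise(500, 8, 8, seed=1), 2).matrix,
    )
    mc.save_cell(tmp_path / "cell.json", cell)
    back = mc.load_cell(tmp_path / "cell.json")
    np.testing.assert_allclose(back.dimensions, cell.dimensions)
    assert back.gain_family == "divisive"
    assert back.gamma == pytest.approx(cell.gamma)
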
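"""Projection distributions, gain estimation, information objectives, gradients."""

import numpy as np
import pytest

import midfield as mf
from midfield.info import BinnedDistributions, BinningScheme


def _make_binned(counts, spike_counts):
    counts = np.asarray(counts, dtype=float)
    B = counts.shape[0]
    scheme = BinningScheme(edges=[np.linspace(0, 1, B + 1)] * counts.ndim)
    return BinnedDistributions(counts=counts, spike_counts=np.asarray(spike_counts, float),
                               scheme=scheme)


class TestProjections:
    def test_basis_vector_extracts_coordinate(self):
        X = np.arange(12.0).reshape(3, 4)
        e2 = np.eye(4)[2]
        np.testing.assert_allclose(mf.project_stimuli(X, e2[None])[:, 0], X[:, 2])

    def test_linearity(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 6))
        v = rng.standard_normal(6)
        np.testing.assert_allclose(
            mf.project_stimuli(X, (2 * v)[None]), 2 * mf.project_stimuli(X, v[None])
        )

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 5))
        V = rng.standard_normal((2, 5))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        np.testing.assert_allclose(
            mf.project_stimuli(X, R @ V), mf.project_stimuli(X, V) @ R.T, atol=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mf.project_stimuli(np.zeros((3, 4)), np.zeros((1, 5)))


class TestBinDistributions:
    def test_point_mass(self):
        P = np.full((50, 1), 0.5)
        bd = mf.bin_distributions(P, np.ones(50, dtype=int), 4)
        assert bd.P_x.max() == 1.0
        assert bd.P_x_spike.max() == 1.0

    def test_spikes_concentrated_in_one_bin(self):
        x = np.linspace(0, 1, 100)[:, None]
        y = np.zeros(100, dtype=int)
        y[:10] = 1  # all spikes in the lowest bin
        bd = mf.bin_distributions(x, y, 10)
        assert bd.P_x_spike[0] == pytest.approx(1.0)
        assert bd.P_x_spike[1:].sum() == 0.0

    def test_uniform_spiking_matches_prior(self):
        rng = np.random.default_rng(2)
        P = rng.standard_normal((500, 2))
        bd = mf.bin_distributions(P, np.ones(500, dtype=int), 5)
        np.testing.assert_allclose(bd.P_x, bd.P_x_spike)

    def test_zero_spikes_rejected(self):
        with pytest.raises(ValueError):
            mf.bin_distributions(np.zeros((10, 1)), np.zeros(10, dtype=int), 4)

    def test_distributions_normalized(self):
        rng = np.random.default_rng(3)
        P = rng.standard_normal((300, 3))
        y = rng.poisson(0.5, 300)
        bd = mf.bin_distributions(P, y, 4)
        assert bd.P_x.sum() == pytest.approx(1.0, abs=1e-12)
        assert bd.P_x_spike.sum() == pytest.approx(1.0, abs=1e-12)
        # support inclusion: spikes only where stimuli occurred
        assert np.all(bd.counts[bd.spike_counts > 0] > 0)


class TestGain:
    def test_uninformative_gain_is_flat(self):
        bd = _make_binned([10, 30, 60], [1, 3, 6])
        g = mf.estimate_gain(bd)
        np.testing.assert_allclose(g.values, g.mean_rate)

    def test_two_bin_closed_form(self):
        # P_x = (0.5, 0.5), P_x|spike = (1, 0), rbar = 0.1 -> g = (0.2, 0)
        bd = _make_binned([50, 50], [10, 0])
        g = mf.estimate_gain(bd)
        np.testing.assert_allclose(g.values, [0.2, 0.0], atol=1e-15)

    def test_normalization_identity(self):
        rng = np.random.default_rng(4)
        P = rng.standard_normal((2000, 1))
        y = rng.poisson(np.exp(P[:, 0] * 0.3))
        bd = mf.bin_distributions(P, y, 7)
        g = mf.estimate_gain(bd)
        assert np.nansum(bd.P_x * g.values) == pytest.approx(bd.mean_rate, abs=1e-12)


def _mi_oracle(counts, spike_counts):
    """Independent direct-summation implementation of the KL information."""
    counts = np.asarray(counts, float).ravel()
    spike_counts = np.asarray(spike_counts, float).ravel()
    total = 0.0
    for c, s in zip(counts, spike_counts):
        if s > 0:
            ps = s / spike_counts.sum()
            px = c / counts.sum()
            total += ps * np.log2(ps / px)
    return total


class TestMutualInformation:
    def test_equal_distributions_zero(self):
        bd = _make_binned([10, 20, 30], [1, 2, 3])
        assert mf.mutual_information(bd) == pytest.approx(0.0, abs=1e-15)

    def test_two_bin_one_bit(self):
        bd = _make_binned([50, 50], [7, 0])
        assert mf.mutual_information(bd) == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 100, 5)
        spikes = rng.integers(0, 20, 5)
        spikes[0] = max(spikes[0], 1)
        bd = _make_binned(counts, spikes)
        assert mf.mutual_information(bd) == pytest.approx(
            _mi_oracle(counts, spikes), abs=1e-12
        )

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts = rng.integers(1, 50, 8)
            spikes = rng.integers(0, 10, 8)
            if spikes.sum() == 0:
                spikes[0] = 1
            assert mf.mutual_information(_make_binned(counts, spikes)) >= 0.0


class TestRenyi2:
    def test_equal_distributions_zero(self):
        bd = _make_binned([5, 5, 5], [2, 2, 2])
        assert mf.renyi2_divergence(bd) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_oracle(self):
        # direct formula: log2(sum ps^2 / px) = log2(1 / 0.5) = 1
        bd = _make_binned([50, 50], [9, 0])
        assert mf.renyi2_divergence(bd) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_under_sharpening(self):
        counts = np.array([40, 30, 20, 10], float)
        base = counts / counts.sum()
        point = np.array([0.0, 0.0, 1.0, 0.0])
        vals = []
        for t in np.linspace(0, 1, 21):
            ps = (1 - t) * base + t * point
            bd = _make_binned(counts, ps * 1000)
            vals.append(mf.renyi2_divergence(bd))
        assert np.all(np.diff(vals) >= -1e-12)


class TestInfoPerSpike:
    def test_constant_rate_zero(self):
        assert mf.info_per_spike(np.full(100, 0.7)) == pytest.approx(0.0, abs=1e-15)

    def test_half_indicator_one_bit(self):
        rates = np.zeros(100)
        rates[:50] = 2.0  # r = 2 rbar on half the frames
        assert mf.info_per_spike(rates) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mf.info_per_spike(np.zeros(10))


class TestScaleAndRecombination:
    @pytest.fixture(scope="class")
    def data(self, white_noise_or):
        return white_noise_or

    def test_scale_invariance(self, data):
        X, y, cell = data["X"], data["y"], data["cell"]
        for c in (2.7, -1.3, 0.01):
            v = cell.dimensions[0]
            i1 = mf.mutual_information(mf.bin_distributions((X @ v)[:, None], y, 9))
            i2 = mf.mutual_information(mf.bin_distributions((X @ (c * v))[:, None], y, 9))
            assert abs(i1 - i2) < 1e-9

    def test_invertible_recombination(self, data):
        X, y, cell = data["X"], data["y"], data["cell"]
        V = cell.dimensions
        I0 = mf.mutual_information(mf.bin_distributions(X @ V.T, y, 11))
        rng = np.random.default_rng(6)

        def rotation(theta):
            return np.array([[np.cos(theta), -np.sin(theta)],
                             [np.sin(theta), np.cos(theta)]])

        for _ in range(3):
            # well-conditioned: random rotations with mild anisotropy (cond <= 2)
            A = rotation(rng.uniform(0, 2 * np.pi)) @ np.diag(rng.uniform(0.7, 1.4, 2))
            A = A @ rotation(rng.uniform(0, 2 * np.pi))
            IA = mf.mutual_information(mf.bin_distributions(X @ (A @ V).T, y, 11))
            assert abs(IA - I0) < 0.05 * I0

    def test_data_processing_chain(self, data):
        """I(v1) <= I(v1,v2) <= I_spike within jackknife noise."""
        X, y, cell, rates = data["X"], data["y"], data["cell"], data["rates"]
        part = mf.jackknife_partitions(X.shape[0], 4)
        i1, i2 = [], []
        for f in range(4):
            m = part.train_mask(f)
            i1.append(mf.mutual_information(
                mf.bin_distributions((X[m] @ cell.dimensions[0])[:, None], y[m], 8)))
            i2.append(mf.mutual_information(
                mf.bin_distributions(X[m] @ cell.dimensions.T, y[m], 8)))
        i1, i2 = np.asarray(i1), np.asarray(i2)
        se = lambda v: v.std(ddof=1) / 2.0
        assert i1.mean() <= i2.mean() + 2 * (se(i1) + se(i2))
        assert i2.mean() <= mf.info_per_spike(rates) + 2 * se(i2)


class TestGradient:
    def test_matches_finite_differences(self):
        """Analytic gradient vs central finite differences of the binned
        information along random unit perturbations (relative error < 5%)."""
        rng = np.random.default_rng(0)
        N, D, B = 20000, 20, 11
        X = rng.standard_normal((N, D))
        e1 = np.zeros(D); e1[0] = 1.0
        y = rng.poisson(0.5 * (X @ e1) ** 2)
        v = e1 + 0.3 * rng.standard_normal(D)
        v /= np.linalg.norm(v)
        g = mf.info_gradient(X, y, v[None], 0, B)

        def info(vv):
            return mf.mutual_information(mf.bin_distributions((X @ vv)[:, None], y, B))

        dir_rng = np.random.default_rng(42)
        fd, an = [], []
        for _ in range(10):
            u = dir_rng.standard_normal(D)
            u /= np.linalg.norm(u)
            fd.append(np.mean([(info(v + e * u) - info(v - e * u)) / (2 * e)
                               for e in (0.08, 0.12, 0.16, 0.2, 0.24)]))
            an.append(float(g @ u))
        fd, an = np.asarray(fd), np.asarray(an)
        assert np.linalg.norm(an - fd) / np.linalg.norm(fd) < 0.05

    def test_uninformative_response_gives_noise_level_gradient(self):
        """Constant-rate response: gradient indistinguishable from jackknife noise."""
        rng = np.random.default_rng(1)
        N, D = 8000, 30
        X = rng.standard_normal((N, D))
        y = rng.poisson(0.5, N)  # no stimulus dependence
        v = rng.standard_normal(D); v /= np.linalg.norm(v)
        # jackknife SE of the gradient norm
        part = mf.jackknife_partitions(N, 4)
        norms = [np.linalg.norm(mf.info_gradient(X[part.train_mask(f)],
                                                 y[part.train_mask(f)], v[None], 0, 8))
                 for f in range(4)]
        full = np.linalg.norm(mf.info_gradient(X, y, v[None], 0, 8))
        assert full < 3.0 * np.mean(norms)

    def test_in_subspace_component_shrinks_with_n(self):
        """At the true dimension of a matched cell the gradient vanishes with N."""
        rng = np.random.default_rng(2)
        D = 20
        e1 = np.zeros(D); e1[0] = 1.0
        comps = []
        for N in (5000, 20000, 80000):
            X = rng.standard_normal((N, D))
            y = rng.poisson(0.5 * (X @ e1) ** 2)
            g = mf.info_gradient(X, y, e1[None], 0, 8)
            comps.append(abs(float(g @ e1)) + np.linalg.norm(g - (g @ e1) * e1))
        assert comps[2] < comps[0]

    def test_stencil_variant_agrees_in_direction(self):
        """Both discretizations estimate the same continuum gradient."""
        rng = np.random.default_rng(3)
        N, D = 20000, 20
        X = rng.standard_normal((N, D))
        e1 = np.zeros(D); e1[0] = 1.0
        y = rng.poisson(0.5 * (X @ e1) ** 2)
        w = e1 + 0.3 * rng.standard_normal(D)
        w /= np.linalg.norm(w)
        g1 = mf.info_gradient(X, y, w[None], 0, 8, method="flux")
        g2 = mf.info_gradient(X, y, w[None], 0, 8, method="stencil")
        cos = g1 @ g2 / (np.linalg.norm(g1) * np.linalg.norm(g2))
        assert cos > 0.9

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            mf.info_gradient(np.zeros((0, 4)), np.zeros(0), np.ones((1, 4)), 0, 4)


class TestSufficiency:
    def test_or_cell_projections_capture_most_rate_information(self, white_noise_or):
        """(s1, s2) are sufficient: binned 2D information approaches I_spike."""
        X, y, cell, rates = (white_noise_or[k] for k in ("X", "y", "cell", "rates"))
        i2 = mf.mutual_information(mf.bin_distributions(X @ cell.dimensions.T, y, 11))
        assert i2 >= 0.9 * mf.info_per_spike(rates)


def test_distribution_export_roundtrip(tmp_path, white_noise_or):
    from midfield.info import load_distributions, save_distributions

    X, y, cell = (white_noise_or[k] for k in ("X", "y", "cell"))
    bd = mf.bin_distributions(X @ cell.dimensions.T, y, 7)
    g = mf.estimate_gain(bd)
    save_distributions(tmp_path / "d.h5", bd, gain=g)
    back = load_distributions(tmp_path / "d.h5")
    np.testing.assert_allclose(back.counts, bd.counts)
    np.testing.assert_allclose(back.P_x_spike, bd.P_x_spike)
    assert mf.mutual_information(back) == pytest.approx(mf.mutual_information(bd))
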
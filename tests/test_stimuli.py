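"""Stimulus generators, embedding and jackknife partitions."""

import numpy as np
import pytest
from scipy import stats

import midfield as mf
from midfield.stimuli import (
    JackknifePartition,
    load_spikes,
    load_stimuli,
    save_spikes,
    save_stimuli,
)


class TestWhiteNoise:
    def test_moments_and_normality(self):
        stim = mf.generate_white_noise(10000, 4, 4, seed=1)
        flat = stim.frames.ravel()
        assert abs(flat.mean()) < 0.02
        assert abs(flat.var() - 1.0) < 0.02
        # KS against standard normal on a subsample
        _, p = stats.kstest(flat[::37].astype(np.float64), "norm")
        assert p > 0.01

    def test_determinism(self):
        a = mf.generate_white_noise(100, 3, 3, seed=9)
        b = mf.generate_white_noise(100, 3, 3, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_temporal_independence(self):
        stim = mf.generate_white_noise(50000, 2, 2, seed=2)
        px = stim.frames[:, 0, 0].astype(np.float64)
        for lag in (1, 2, 5):
            r = np.corrcoef(px[:-lag], px[lag:])[0, 1]
            assert abs(r) < 3.0 / np.sqrt(len(px))

    def test_rejects_bad_shape(self):
        with pytest.raises(ValueError):
            mf.generate_white_noise(0, 4, 4)


class TestNaturalistic:
    def test_marginal_is_heavy_tailed(self):
        stim = mf.generate_naturalistic(5000, 8, 8, seed=1)
        assert stats.kurtosis(stim.frames.ravel()) > 0.5

    def test_degenerate_settings_match_white_noise(self):
        stim = mf.generate_naturalistic(
            4000, 6, 6, spectrum_exponent=0.0, nongaussian_transform="identity",
            ar_coeff=0.0, seed=3,
        )
        _, p = stats.kstest(stim.frames.ravel()[::23].astype(np.float64), "norm")
        assert p > 0.01

    def test_neighbor_correlation(self):
        stim = mf.generate_naturalistic(5000, 8, 8, spectrum_exponent=2.0, seed=4)
        a = stim.frames[:, :, :-1].ravel().astype(np.float64)
        b = stim.frames[:, :, 1:].ravel().astype(np.float64)
        assert np.corrcoef(a, b)[0, 1] > 0.3

    @staticmethod
    def _quadratic_t_stats(X, rng, n_pairs=10):
        """t statistics of the quadratic term of <s.w | s.u> over random pairs."""
        ts = []
        for _ in range(n_pairs):
            u = rng.standard_normal(X.shape[1]); u /= np.linalg.norm(u)
            w = rng.standard_normal(X.shape[1]); w /= np.linalg.norm(w)
            x1 = X @ u
            target = X @ w
            A = np.column_stack([np.ones_like(x1), x1, x1**2])
            coef, *_ = np.linalg.lstsq(A, target, rcond=None)
            resid = target - A @ coef
            sigma2 = float(resid @ resid) / (len(x1) - 3)
            cov = sigma2 * np.linalg.inv(A.T @ A)
            ts.append(abs(coef[2]) / np.sqrt(cov[2, 2]))
        return np.asarray(ts)

    def test_conditional_mean_is_nonlinear(self, naturalistic_small):
        """<s|s1> along random projections has a significant quadratic part.

        This non-Gaussian property is what biases sequential searches; the
        matched Gaussian ensemble (identity transform) has linear conditional
        means, so its quadratic terms stay at noise level.
        """
        X = naturalistic_small["X"].astype(np.float64)[::3]  # thin: decorrelate rows
        t_nat = self._quadratic_t_stats(X, np.random.default_rng(0))
        stim_g = mf.generate_naturalistic(5000, 6, 6, seed=7,
                                          nongaussian_transform="identity")
        Xg = mf.embed_spatiotemporal(stim_g, 2).matrix.astype(np.float64)[::3]
        t_gauss = self._quadratic_t_stats(Xg, np.random.default_rng(0))
        assert t_nat.max() > 3.0
        assert t_nat.max() > t_gauss.max()

    def test_invalid_transform_rejected(self):
        with pytest.raises(ValueError):
            mf.generate_naturalistic(10, 4, 4, nongaussian_transform="cauchy")


class TestEmbedding:
    def test_indexing_convention(self):
        frames = np.array([[[1.0]], [[2.0]], [[3.0]]])
        emb = mf.embed_spatiotemporal(mf.StimulusEnsemble(frames), n_lags=2)
        np.testing.assert_allclose(emb.matrix, [[1, 2], [2, 3]])
        np.testing.assert_array_equal(emb.frame_index_map, [1, 2])

    def test_single_lag_is_identity(self):
        stim = mf.generate_white_noise(20, 3, 4, seed=0)
        emb = mf.embed_spatiotemporal(stim, 1)
        np.testing.assert_allclose(emb.matrix, stim.frames.reshape(20, 12))

    def test_dimensionality(self):
        stim = mf.generate_white_noise(10, 16, 16, seed=0)
        assert mf.embed_spatiotemporal(stim, 3).n_dim == 768

    def test_embedding_is_lossless(self):
        stim = mf.generate_white_noise(30, 2, 2, seed=1)
        emb = mf.embed_spatiotemporal(stim, 3)
        # frame t appears as the final lag of row t - n_lags + 1
        for row in range(emb.n_samples):
            final_frame = emb.matrix[row, -4:].reshape(2, 2)
            np.testing.assert_allclose(final_frame, stim.frames[row + 2])
        # the first rows carry the initial frames, so the full movie is recoverable
        first = emb.matrix[0].reshape(3, 2, 2)
        np.testing.assert_allclose(first, stim.frames[:3])

    def test_too_few_frames_rejected(self):
        stim = mf.generate_white_noise(2, 2, 2, seed=0)
        with pytest.raises(ValueError):
            mf.embed_spatiotemporal(stim, 3)


class TestJackknife:
    def test_contiguous_quarters(self):
        part = mf.jackknife_partitions(8, 4)
        blocks = [part.holdout_indices(k).tolist() for k in range(4)]
        assert blocks == [[0, 1], [2, 3], [4, 5], [6, 7]]

    def test_partition_property(self):
        part = mf.jackknife_partitions(103, 4)
        all_rows = np.concatenate([part.holdout_indices(k) for k in range(4)])
        assert sorted(all_rows.tolist()) == list(range(103))
        for k in range(4):
            train = set(part.train_indices(k).tolist())
            hold = set(part.holdout_indices(k).tolist())
            assert not train & hold

    def test_uneven_split_sizes(self):
        part = mf.jackknife_partitions(10, 4)
        sizes = sorted(len(part.holdout_indices(k)) for k in range(4))
        assert sizes == [2, 2, 3, 3]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            mf.jackknife_partitions(3, 4)

    def test_json_roundtrip(self):
        part = mf.jackknife_partitions(10, 4)
        back = JackknifePartition.from_json(part.to_json())
        np.testing.assert_array_equal(part.boundaries, back.boundaries)


class TestIO:
    def test_hdf5_roundtrip(self, tmp_path):
        stim = mf.generate_white_noise(10, 4, 4, seed=5)
        save_stimuli(tmp_path / "s.h5", stim)
        back = load_stimuli(tmp_path / "s.h5")
        np.testing.assert_allclose(back.frames, stim.frames)
        assert back.ensemble_kind == "white_noise"
        assert back.seed == 5

    def test_binary_roundtrip(self, tmp_path):
        stim = mf.generate_white_noise(10, 4, 4, seed=5)
        save_stimuli(tmp_path / "s.bin", stim)
        back = load_stimuli(tmp_path / "s.bin")
        np.testing.assert_allclose(back.frames, stim.frames)

    def test_spike_text_roundtrip(self, tmp_path):
        y = mf.SpikeResponse(np.array([0, 1, 3, 0, 2]))
        save_spikes(tmp_path / "y.txt", y)
        back = load_spikes(tmp_path / "y.txt")
        np.testing.assert_array_equal(back.counts, y.counts)
        assert back.mean_rate_per_frame == pytest.approx(1.2)
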
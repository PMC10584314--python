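"""Reducers: CAR arithmetic, PCA/MDS/LLE against independent oracles,
canonical-correlation fitting and its invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

from ssvepsr.dimred import (
    car_reduce,
    cca_fit,
    cca_reduce,
    lle_reduce,
    lle_weights,
    mds_reduce,
    pca_reduce,
)
from ssvepsr.signal_model import EEGEpoch, make_template_bank, time_axis

NAMES8 = ("POz", "PO3", "PO4", "PO5", "PO6", "Oz", "O1", "O2")


def _epoch(data, fs=1000.0):
    names = NAMES8[: data.shape[0]]
    return EEGEpoch(np.asarray(data, float), fs=fs, channel_names=names)


class TestCAR:
    def test_constant_channels_cancel(self):
        ep = _epoch(np.full((8, 100), 3.7))
        assert np.allclose(car_reduce(ep).values, 0.0)

    def test_reference_minus_mean_arithmetic(self):
        data = np.tile(np.arange(1.0, 9.0)[:, None], (1, 50))
        ep = _epoch(data)
        out = car_reduce(ep, reference_channel="PO6")  # channel value 5
        assert np.allclose(out.values, 5.0 - 4.5)

    def test_sinusoidal_reference_keeps_spectral_line(self):
        rng = np.random.default_rng(4)
        fs, n = 1000.0, 2000
        t = time_axis(n, fs)
        data = rng.standard_normal((8, n))
        data[5] = np.sin(2 * np.pi * 10 * t)  # Oz
        out = car_reduce(_epoch(data), "Oz")
        amp = np.abs(np.fft.rfft(out.values))
        freqs = np.fft.rfftfreq(n, 1 / fs)
        assert freqs[np.argmax(amp)] == pytest.approx(10.0)

    def test_unknown_channel_raises(self):
        with pytest.raises(KeyError):
            car_reduce(_epoch(np.zeros((8, 10))), "Cz")


class TestPCA:
    def test_rank1_recovery(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(0.5, 1.5, 8)
        s = rng.standard_normal(500)
        out = pca_reduce(_epoch(np.outer(g, s)))
        r = np.corrcoef(out.values, s)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_noise_explains_about_one_eighth(self):
        rng = np.random.default_rng(1)
        out = pca_reduce(_epoch(rng.standard_normal((8, 4000))))
        assert out.meta["explained_variance_fraction"] == pytest.approx(1 / 8, abs=0.03)

    def test_score_variance_beats_random_projections(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((8, 300)) * np.arange(1, 9)[:, None]
        ep = _epoch(data)
        out = pca_reduce(ep)
        centred = data - data.mean(axis=1, keepdims=True)
        best_random = 0.0
        for _ in range(1000):
            w = rng.standard_normal(8)
            w /= np.linalg.norm(w)
            best_random = max(best_random, np.var(w @ centred))
        assert np.var(out.values) >= best_random - 1e-9

    def test_direction_matches_power_iteration(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 400)) * np.array([3, 1, 1, 1, 1, 0.5])[:, None]
        ep = _epoch(data[:6])
        centred = data - data.mean(axis=1, keepdims=True)
        cov = centred @ centred.T / (399)
        w = np.ones(6) / np.sqrt(6)
        for _ in range(2000):
            w = cov @ w
            w /= np.linalg.norm(w)
        loading = pca_reduce(ep).meta["loading"]
        assert min(np.linalg.norm(loading - w), np.linalg.norm(loading + w)) < 1e-6

    def test_degenerate_epoch_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(_epoch(np.zeros((4, 100))))


class TestMDS:
    def test_collinear_points_preserve_distances(self):
        s = np.linspace(0, 1, 60)
        direction = np.array([1.0, 2.0, -1.0])
        data = (direction[:, None] * s[None, :]) + 5.0
        out = mds_reduce(_epoch(data, fs=60.0))
        orig = np.abs(s[:, None] - s[None, :]) * np.linalg.norm(direction)
        emb = np.abs(out.values[:, None] - out.values[None, :])
        np.testing.assert_allclose(emb, orig, atol=1e-9)

    def test_duplicated_samples_share_coordinates(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((4, 30))
        data = np.concatenate([base, base[:, :1].repeat(5, axis=1)], axis=1)
        out = mds_reduce(_epoch(data, fs=35.0))
        dup = out.values[-5:]
        assert np.ptp(dup) < 1e-9
        assert abs(dup[0] - out.values[0]) < 1e-9

    def test_matches_double_centred_gram_oracle(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal((8, 2))
        src = rng.standard_normal((2, 200))
        data = g @ src
        out = mds_reduce(_epoch(data, fs=200.0), max_points=500)
        pts = data.T
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        j = np.eye(200) - 1.0 / 200
        b = -0.5 * j @ d2 @ j
        evals, evecs = np.linalg.eigh(b)
        coord = evecs[:, -1] * np.sqrt(evals[-1])
        dev = min(
            np.max(np.abs(out.values - coord)), np.max(np.abs(out.values + coord))
        )
        assert dev < 1e-8

    def test_subsampling_returns_full_length(self):
        rng = np.random.default_rng(6)
        ep = _epoch(rng.standard_normal((4, 500)))
        out = mds_reduce(ep, max_points=100)
        assert len(out.values) == 500
        assert out.meta["n_used"] <= 100


class TestLLE:
    def _curve_epoch(self, n=500):
        t = np.linspace(0, 1, n)
        data = np.vstack(
            [
                t,
                t**2,
                np.sin(2 * t),
                np.cos(1.5 * t),
                t**3,
                np.sin(3 * t + 1),
                np.cos(0.5 * t),
                0.5 * t,
            ]
        )
        return EEGEpoch(data, fs=float(n), channel_names=NAMES8), t

    def test_weight_rows_sum_to_one(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((80, 5))
        w = lle_weights(pts, k=10)
        sums = np.asarray(w.sum(axis=1)).ravel()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        # zero outside neighbourhoods: exactly k entries per row
        assert (w.indptr[1:] - w.indptr[:-1] == 10).all()

    def test_embedding_constraints(self):
        ep, _ = self._curve_epoch(300)
        out = lle_reduce(ep, K=12)
        assert abs(out.values.mean()) < 1e-6
        assert out.values.std() == pytest.approx(1.0, abs=1e-6)

    def test_recovers_curve_parameter(self):
        ep, t = self._curve_epoch(500)
        out = lle_reduce(ep, K=12, max_points=1000)
        rc = abs(spearmanr(out.values, t).statistic)
        assert rc >= 0.99

    def test_agrees_with_sklearn_embedding(self):
        from sklearn.manifold import LocallyLinearEmbedding

        ep, _ = self._curve_epoch(400)
        ours = lle_reduce(ep, K=12, max_points=1000)
        ref = LocallyLinearEmbedding(n_neighbors=12, n_components=1, reg=1e-3)
        emb = ref.fit_transform(ep.data.T).ravel()
        r = abs(np.corrcoef(ours.values, emb)[0, 1])
        assert r > 0.99

    def test_k_too_large_rejected(self):
        ep, _ = self._curve_epoch(30)
        with pytest.raises(ValueError):
            lle_reduce(ep, K=40)


class TestCCAFit:
    def test_signal_in_template_span_gives_rho_one(self):
        fs, n = 1000.0, 2000
        t = time_axis(n, fs)
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = make_template_bank([10], k=1, fs=fs, n_samples=n)[10]
        assert cca_fit(x, y).rho == pytest.approx(1.0, abs=1e-6)

    def test_incommensurate_sinusoids_near_zero(self):
        fs, n = 1000.0, 2000
        t = time_axis(n, fs)
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = make_template_bank([25], k=1, fs=fs, n_samples=n)[25]
        assert cca_fit(x, y).rho <= 0.05

    def test_matches_brute_force_maximization(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 400))
        y = rng.standard_normal((2, 400))

        def neg_corr(w):
            a = w[:4] @ x
            b = w[4:] @ y
            a = a - a.mean()
            b = b - b.mean()
            d = np.linalg.norm(a) * np.linalg.norm(b)
            return 0.0 if d == 0 else -(a @ b) / d

        best = 0.0
        for i in range(20):
            w0 = np.random.default_rng(i).standard_normal(6)
            res = minimize(
                neg_corr,
                w0,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
            )
            best = max(best, -res.fun)
        assert cca_fit(x, y).rho == pytest.approx(best, abs=1e-4)

    def test_invariant_to_invertible_channel_remixing(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((4, 600))
        y = rng.standard_normal((3, 600))
        m = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        assert cca_fit(m @ x, y).rho == pytest.approx(cca_fit(x, y).rho, abs=1e-6)

    def test_unit_variance_projections_and_sign_convention(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((4, 500))
        y = rng.standard_normal((2, 500))
        proj = cca_fit(x, y)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean(axis=1, keepdims=True)
        assert np.var(proj.wx @ xc, ddof=1) == pytest.approx(1.0, rel=1e-6)
        assert np.var(proj.wy @ yc, ddof=1) == pytest.approx(1.0, rel=1e-6)
        assert (proj.wx @ xc) @ yc[0] >= 0

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cca_fit(np.zeros((2, 10)), np.zeros((2, 11)))


class TestCCAReduce:
    def test_rank1_projection_recovers_waveform(self, rank1_epoch):
        ep = rank1_epoch(10.0)
        bank = make_template_bank([10.0], k=2, fs=ep.fs, n_samples=ep.n_samples)
        out = cca_reduce(ep, bank, 10.0)
        assert len(out.values) == ep.n_samples
        r = np.corrcoef(out.values, ep.data[0])[0, 1]
        assert abs(r) >= 0.999

    def test_matched_frequency_has_larger_line(self):
        from ssvepsr.signal_model import SyntheticConfig, generate_epoch

        ep = generate_epoch(
            SyntheticConfig(f_target=7.0, duration=2.0, snr_db=10, seed=21)
        )
        bank = make_template_bank([7.0, 13.0], k=2, fs=ep.fs, n_samples=ep.n_samples)
        t = time_axis(ep.n_samples, ep.fs)
        z = np.exp(-2j * np.pi * 7.0 * t)

        def line(values):
            v = values - values.mean()
            v = v / np.linalg.norm(v)
            return abs(z @ v)

        amp_match = line(cca_reduce(ep, bank, 7.0).values)
        amp_mismatch = line(cca_reduce(ep, bank, 13.0).values)
        assert amp_match > amp_mismatch


class TestOffsetInvariance:
    """Adding a common constant to every channel does not change the
    mean-centred reducers; CAR follows its literal arithmetic."""

    def test_pca_mds_cca_offset_invariant(self, rank1_epoch):
        ep = rank1_epoch(9.0, duration=0.5, fs=400)
        shifted = EEGEpoch(
            ep.data + 42.0, fs=ep.fs, channel_names=ep.channel_names, true_freq=9.0
        )
        bank = make_template_bank([9.0], k=2, fs=ep.fs, n_samples=ep.n_samples)
        np.testing.assert_allclose(
            pca_reduce(ep).values, pca_reduce(shifted).values, atol=1e-8
        )
        np.testing.assert_allclose(
            mds_reduce(ep).values, mds_reduce(shifted).values, atol=1e-8
        )
        np.testing.assert_allclose(
            cca_reduce(ep, bank, 9.0).values,
            cca_reduce(shifted, bank, 9.0).values,
            atol=1e-8,
        )

    def test_car_shifts_cancel_in_the_mean(self):
        rng = np.random.default_rng(13)
        data = rng.standard_normal((8, 100))
        a = car_reduce(_epoch(data))
        b = car_reduce(_epoch(data + 7.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
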
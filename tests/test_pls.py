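"""NIPALS PLS1, segment cross-validation, and the metric suite."""

import numpy as np
import pandas as pd
import pytest

from aquaphot.dataset import SpectralDataset
from aquaphot.exceptions import (
    DegenerateResponseError,
    IncompatibleGridError,
    LimitExceededError,
)
from aquaphot.pls import (
    PLSTimeRegression,
    _folds,
    cross_validate,
    fit_plsr,
    roughness,
)


def single_channel_dataset(rng, n=30, p=50, channel=7, slope=3.0):
    """Only one channel varies; the response is exactly linear in it."""
    static = np.abs(rng.normal(1.0, 0.2, p))
    t = rng.normal(0, 1, n)
    X = np.tile(static, (n, 1))
    X[:, channel] += t
    y = slope * t + 5.0
    wl = np.linspace(1300, 1600, p)
    return SpectralDataset(wl, X), y


class TestFit:
    def test_noiseless_single_channel_is_exact(self, ):
        ds, y = single_channel_dataset(np.random.default_rng(0))
        res = fit_plsr(ds, y=y, n_lv=1)
        assert res.r2_calibration == pytest.approx(1.0, abs=1e-12)
        assert res.sec <= 1e-8

    def test_regression_vector_localised_on_informative_channel(self):
        ds, y = single_channel_dataset(np.random.default_rng(1))
        res = fit_plsr(ds, y=y, n_lv=1)
        b = np.abs(res.coef)
        assert int(np.argmax(b)) == 7
        assert b[7] > 100 * np.delete(b, 7).max()

    def test_constant_response_rejected(self, bare_dataset):
        ds = bare_dataset(np.random.default_rng(0).normal(size=(10, 50)))
        with pytest.raises(DegenerateResponseError):
            fit_plsr(ds, y=np.ones(10), n_lv=1)

    def test_latent_variable_cap(self, bare_dataset):
        ds = bare_dataset(np.random.default_rng(0).normal(size=(40, 50)))
        y = np.arange(40.0)
        with pytest.raises(LimitExceededError, match="15"):
            fit_plsr(ds, y=y, n_lv=16)

    def test_scores_orthogonal(self, bare_dataset):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 50))
        y = X @ rng.normal(size=50) + rng.normal(0, 0.5, 40)
        res = fit_plsr(bare_dataset(X), y=y, n_lv=8)
        G = res.scores.T @ res.scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off <= 1e-8 * np.abs(np.diag(G)).max()

    def test_sec_never_increases_with_rank(self, bare_dataset):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 50))
        y = X @ rng.normal(size=50) + rng.normal(0, 0.5, 40)
        ds = bare_dataset(X)
        secs = [fit_plsr(ds, y=y, n_lv=a).sec for a in range(1, 11)]
        assert all(np.diff(secs) <= 1e-10)

    def test_constant_offset_invariance(self, bare_dataset):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 50))
        y = X @ rng.normal(size=50)
        r1 = fit_plsr(bare_dataset(X), y=y, n_lv=4)
        r2 = fit_plsr(bare_dataset(X + 3.7), y=y, n_lv=4)
        np.testing.assert_allclose(r1.coef, r2.coef, atol=1e-10)
        np.testing.assert_allclose(r1.fitted_values, r2.fitted_values, atol=1e-8)

    def test_matches_sklearn_nipals(self, bare_dataset):
        """Independent oracle: scikit-learn's PLS regression coefficients."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 50))
        y = X @ rng.normal(size=50) + rng.normal(0, 0.5, 40)
        mine = fit_plsr(bare_dataset(X), y=y, n_lv=4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(mine.coef, ref.coef_.ravel(), atol=1e-10)


class TestPredict:
    def test_in_sample_rmse_equals_sec(self, bare_dataset):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 50))
        y = X @ rng.normal(size=50) + rng.normal(0, 1.0, 30)
        ds = bare_dataset(X)
        res = fit_plsr(ds, y=y, n_lv=3)
        rmse = np.sqrt(((y - res.predict(ds)) ** 2).mean())
        assert rmse == pytest.approx(res.sec)

    def test_mean_spectrum_predicts_mean_response(self, bare_dataset):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 50))
        y = X @ rng.normal(size=50)
        res = fit_plsr(bare_dataset(X), y=y, n_lv=3)
        assert res.predict(X.mean(axis=0, keepdims=True))[0] == pytest.approx(
            y.mean())

    def test_grid_mismatch_raises(self, bare_dataset):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 50))
        res = fit_plsr(bare_dataset(X), y=X[:, 0], n_lv=1)
        other = SpectralDataset(np.linspace(900, 1700, 50), X)
        with pytest.raises(IncompatibleGridError):
            res.predict(other)


class TestCrossValidate:
    def test_fold_structure(self):
        folds = _folds(12, 6, "block")
        assert len(folds) == 2
        assert sorted(np.concatenate(folds).tolist()) == list(range(12))
        folds = _folds(15, 6, "block")  # trailing short block kept
        assert [len(f) for f in folds] == [6, 6, 3]
        vb = _folds(12, 6, "venetian")
        assert sorted(np.concatenate(vb).tolist()) == list(range(12))

    def test_noiseless_secv_vanishes(self):
        ds, y = single_channel_dataset(np.random.default_rng(9))
        cv = cross_validate(ds, y=y, n_lv_max=2, segment=6)
        assert cv.metrics["secv"].iloc[0] <= 1e-6

    def test_secv_tracks_noise_scale(self):
        sigma = 0.5
        secvs = []
        for s in range(50):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(150, 20))
            y = 2 * X[:, 3] - X[:, 11] + rng.normal(0, sigma, 150)
            ds = SpectralDataset(np.linspace(1300, 1600, 20), X)
            secvs.append(cross_validate(ds, y=y, n_lv_max=5, segment=6).secv)
        assert 0.8 * sigma <= np.median(secvs) <= 1.3 * sigma

    def test_uninformative_spectra_do_not_validate(self):
        r2s = []
        for s in range(50):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(60, 50))
            y = rng.normal(size=60)
            ds = SpectralDataset(np.linspace(1300, 1600, 50), X)
            r2s.append(cross_validate(ds, y=y, n_lv_max=5, segment=6).r2_cv)
        assert np.median(r2s) <= 0.1

    def test_invalid_segment_raises(self, bare_dataset):
        ds = bare_dataset(np.random.default_rng(0).normal(size=(20, 50)))
        with pytest.raises(LimitExceededError):
            cross_validate(ds, y=np.arange(20.0), segment=0)


def test_roughness_flags_jagged_vectors():
    smooth = np.sin(np.linspace(0, np.pi, 50))
    jagged = smooth + 0.5 * (-1.0) ** np.arange(50)
    assert roughness(jagged) > 10 * roughness(smooth)
    assert roughness(np.zeros(50)) == 0.0
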
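"""SNV, centering, group averaging, difference spectra, per-channel z-scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaphot.dataset import SpectralDataset, crop_region, nearest_channel
from aquaphot.exceptions import (
    DegenerateChannelError,
    DegenerateSpectrumError,
    InsufficientDataError,
    MissingGroupError,
    SchemaError,
)
from aquaphot.preprocess import (
    average_by,
    difference_spectrum,
    mean_center,
    snv,
    standardize_per_wavelength,
)
from aquaphot.synthetic import SyntheticConfig, generate_spectra


class TestSNV:
    def test_symmetric_row(self):
        ds3 = SpectralDataset(np.array([1.0, 2.0, 3.0]),
                              np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(snv(ds3).absorbance[0], [-1.0, 0.0, 1.0])

    def test_constant_row_raises_with_row_index(self, bare_dataset):
        X = np.random.default_rng(0).normal(size=(3, 50))
        X[1] = 0.7
        with pytest.raises(DegenerateSpectrumError, match="row 1"):
            snv(bare_dataset(X))

    def test_row_moments(self, bare_dataset):
        X = np.random.default_rng(2).normal(1.0, 0.3, size=(20, 50))
        out = snv(bare_dataset(X)).absorbance
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    @given(
        gain=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance(self, gain, offset, seed):
        wl = np.linspace(1300, 1600, 30)
        X = np.random.default_rng(seed).normal(1.0, 0.2, size=(4, 30))
        base = SpectralDataset(wl, X)
        scaled = SpectralDataset(wl, gain * X + offset)
        np.testing.assert_allclose(
            snv(scaled).absorbance, snv(base).absorbance, atol=1e-8
        )


class TestMeanCenter:
    def test_small_example(self):
        out = mean_center(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[-1.0, -1.0], [1.0, 1.0]])

    def test_idempotent_on_centered(self):
        X = np.random.default_rng(0).normal(size=(6, 5))
        X -= X.mean(axis=0)
        np.testing.assert_allclose(mean_center(X), X, atol=1e-12)

    def test_output_column_means_zero(self):
        X = np.random.default_rng(1).normal(3.0, 2.0, size=(11, 7))
        assert np.abs(mean_center(X).mean(axis=0)).max() <= 1e-12

    def test_single_row_raises(self):
        with pytest.raises(InsufficientDataError):
            mean_center(np.ones((1, 5)))


class TestAverageBy:
    def test_mean_is_idempotent_for_identical_spectra(self, grid50):
        X = np.tile(np.random.default_rng(0).normal(size=50), (2, 1))
        ds = SpectralDataset(grid50, X, pd.DataFrame({"condition": ["CF", "CF"]}))
        out = average_by(ds, ["condition"])
        assert out.n_spectra == 1
        np.testing.assert_allclose(out.absorbance[0], X[0])

    def test_two_groups(self, grid50):
        X = np.vstack([np.zeros(50), np.ones(50)])
        ds = SpectralDataset(grid50, X, pd.DataFrame({"condition": ["a", "b"]}))
        out = average_by(ds, ["condition"])
        assert out.n_spectra == 2
        assert set(out.absorbance[:, 0]) == {0.0, 1.0}

    def test_condition_day_groups_count(self, small_config):
        ds = generate_spectra(small_config)
        out = average_by(ds, ["condition", "day"])
        assert out.n_spectra == 2 * 15

    def test_unknown_key_raises(self, bare_dataset):
        with pytest.raises(SchemaError):
            average_by(bare_dataset(np.ones((2, 50))), ["nope"])

    def test_matches_brute_force_means(self, small_config):
        ds = generate_spectra(small_config)
        out = average_by(ds, ["condition", "day"])
        row = out.meta.sample(1, random_state=0).iloc[0]
        manual = ds.where(condition=row["condition"], day=row["day"]).absorbance
        idx = out.meta[(out.meta["condition"] == row["condition"])
                       & (out.meta["day"] == row["day"])].index[0]
        np.testing.assert_allclose(out.absorbance[idx], manual.mean(axis=0))


class TestDifferenceSpectrum:
    def test_same_day_is_zero(self, small_config):
        ds = generate_spectra(small_config)
        d = difference_spectrum(ds, "CF", 3, 3)
        np.testing.assert_allclose(d.delta, 0.0, atol=1e-12)

    def test_single_channel_shift(self, grid50):
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.2, 50)
        X = np.vstack([base, base.copy()])
        X[1, 7] += 0.5
        ds = SpectralDataset(grid50, X, pd.DataFrame(
            {"condition": ["CF", "CF"], "day": [1, 2]}))
        d = difference_spectrum(ds, "CF", 2, 1, apply_snv=False)
        assert d.delta[7] == pytest.approx(0.5)
        mask = np.ones(50, dtype=bool)
        mask[7] = False
        np.testing.assert_allclose(d.delta[mask], 0.0, atol=1e-12)

    def test_antisymmetry(self, small_config):
        ds = generate_spectra(small_config)
        fwd = difference_spectrum(ds, "SCF", 5, 1)
        bwd = difference_spectrum(ds, "SCF", 1, 5)
        np.testing.assert_allclose(fwd.delta, -bwd.delta, atol=1e-12)

    def test_missing_day_raises(self, small_config):
        ds = generate_spectra(small_config)
        with pytest.raises(MissingGroupError):
            difference_spectrum(ds, "CF", 99, 1)

    def test_cf_free_water_decline_peaks_at_1404(self):
        """The generator programs the steepest monotone decline at the free
        water band: the day-4-vs-1 difference must bottom out there."""
        hits = 0
        for seed in range(6):
            cfg = SyntheticConfig(seed=seed)  # full design: 24 fruit-day means
            ds = crop_region(generate_spectra(cfg), 1300, 1600)
            d = difference_spectrum(ds, "CF", 4, 1)
            hits += int(np.argmin(d.delta)) == nearest_channel(ds, 1404)
        assert hits >= 4


class TestStandardizePerWavelength:
    def test_two_spectra(self, grid50):
        ds = SpectralDataset(grid50, np.vstack([np.zeros(50), np.ones(50)]))
        out = standardize_per_wavelength(ds).absorbance
        np.testing.assert_allclose(out[0], -1 / np.sqrt(2), atol=1e-12)
        np.testing.assert_allclose(out[1], +1 / np.sqrt(2), atol=1e-12)

    def test_column_moments(self, bare_dataset):
        X = np.random.default_rng(3).normal(2.0, 0.5, size=(30, 50))
        out = standardize_per_wavelength(bare_dataset(X)).absorbance
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_spectrum_raises(self, bare_dataset):
        with pytest.raises(InsufficientDataError):
            standardize_per_wavelength(bare_dataset(np.ones((1, 50))))

    def test_dead_channel_raises(self, bare_dataset):
        X = np.random.default_rng(0).normal(size=(5, 50))
        X[:, 9] = 1.23
        with pytest.raises(DegenerateChannelError):
            standardize_per_wavelength(bare_dataset(X))
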
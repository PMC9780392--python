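"""SIMCA class models, interclass distance, discriminating power, classification."""

import numpy as np
import pandas as pd
import pytest

from aquaphot.dataset import SpectralDataset, crop_region, nearest_channel
from aquaphot.exceptions import (
    IncompatibleGridError,
    NeedTwoClassesError,
    UndersizedClassError,
)
from aquaphot.simca import SIMCA, SIMCAResults, fit_simca
from aquaphot.synthetic import SyntheticConfig, generate_spectra


def gaussian_classes(rng, n_classes=5, n=12, sep=1.0, noise=0.1, p=50):
    """Classes with distinct means along different channels + isotropic noise."""
    blocks = []
    for c in range(n_classes):
        mu = np.zeros(p)
        mu[5 + 8 * c] = sep * (c + 1)
        blocks.append((c, mu + rng.normal(0, noise, (n, p))))
    return blocks


class TestFit:
    def test_exact_low_rank_class(self, grid50):
        rng = np.random.default_rng(0)
        # both classes exactly rank 2 around their means
        def rank2(mu):
            basis = rng.normal(size=(2, 50))
            coef = rng.normal(size=(10, 2))
            return mu + coef @ basis
        X = np.vstack([rank2(np.zeros(50)), rank2(np.full(50, 5.0))])
        ds = SpectralDataset(grid50, X, pd.DataFrame({"day": [0] * 10 + [1] * 10}))
        res = fit_simca(ds)
        assert [m.k for m in res.class_models] == [2, 2]
        assert res.s2_pooled[0, 0] < 1e-20
        assert res.s2_pooled[1, 1] < 1e-20

    def test_single_class_rejected(self, grid50):
        ds = SpectralDataset(grid50, np.random.default_rng(0).normal(size=(6, 50)),
                             pd.DataFrame({"day": [1] * 6}))
        with pytest.raises(NeedTwoClassesError):
            fit_simca(ds)

    def test_undersized_class_rejected(self, grid50):
        ds = SpectralDataset(grid50, np.random.default_rng(0).normal(size=(8, 50)),
                             pd.DataFrame({"day": [0] * 6 + [1] * 2}))
        with pytest.raises(UndersizedClassError):
            fit_simca(ds)


class TestInterclassDistance:
    def test_self_distance_zero(self, labelled_dataset):
        rng = np.random.default_rng(0)
        res = fit_simca(labelled_dataset(gaussian_classes(rng, n_classes=2)))
        assert res.interclass_distance(0, 0) == 0.0
        assert res.interclass_distance(0, 1) == res.interclass_distance(1, 0)

    def test_identical_distributions_score_near_zero(self, labelled_dataset):
        dists = []
        for s in range(100):
            rng = np.random.default_rng(s)
            blocks = [(0, rng.normal(0, 0.1, (12, 50))),
                      (1, rng.normal(0, 0.1, (12, 50)))]
            res = fit_simca(labelled_dataset(blocks))
            dists.append(res.interclass_distance(0, 1))
        assert np.median(dists) < 0.3

    def test_separated_classes_score_high(self, labelled_dataset):
        rng = np.random.default_rng(7)
        blocks = gaussian_classes(rng, n_classes=2, sep=1.0, noise=0.1)
        res = fit_simca(labelled_dataset(blocks))
        assert res.interclass_distance(0, 1) > 3

    def test_distance_grows_with_separation(self, labelled_dataset):
        meds = []
        for sep in (0.2, 1.0, 5.0):
            vals = []
            for s in range(10):
                rng = np.random.default_rng(100 + s)
                blocks = gaussian_classes(rng, n_classes=2, sep=sep, noise=0.1)
                res = fit_simca(labelled_dataset(blocks))
                vals.append(res.interclass_distance(0, 1))
            meds.append(np.median(vals))
        assert meds[0] < meds[1] < meds[2]


class TestClassify:
    def test_class_mean_is_assigned_to_its_class(self, labelled_dataset):
        rng = np.random.default_rng(1)
        blocks = gaussian_classes(rng, n_classes=3, sep=2.0, noise=0.05)
        res = fit_simca(labelled_dataset(blocks))
        for c, Xc in blocks:
            out = res.classify(Xc.mean(axis=0))
            assert out["label"].iloc[0] == c
            assert out[f"d_{c}"].iloc[0] < 1.0

    def test_well_separated_heldout_is_perfect(self, labelled_dataset):
        for s in range(10):
            rng = np.random.default_rng(s)
            train = labelled_dataset(gaussian_classes(rng, sep=1.0, noise=0.1))
            test = labelled_dataset(gaussian_classes(rng, n=6, sep=1.0, noise=0.1))
            res = fit_simca(train)
            assert res.accuracy(test) == 1.0

    def test_permuted_labels_give_chance_accuracy(self, labelled_dataset):
        accs = []
        for s in range(50):
            rng = np.random.default_rng(1000 + s)
            blocks = gaussian_classes(rng, n_classes=5, n=10, sep=1.0, noise=0.1)
            X = np.vstack([b for _, b in blocks])
            days = rng.permutation(np.repeat(np.arange(5), 10))
            train = SpectralDataset(np.linspace(1300, 1600, 50), X,
                                    pd.DataFrame({"day": days}))
            test = labelled_dataset(
                [(c, b) for c, b in gaussian_classes(rng, n_classes=5, n=4,
                                                     sep=1.0, noise=0.1)])
            test_labels = rng.permutation(np.repeat(np.arange(5), 4))
            test.meta["day"] = test_labels
            accs.append(fit_simca(train).accuracy(test))
        mean_acc = np.mean(accs)
        # binomial CI around chance (0.2) for 50 runs x 20 samples
        assert abs(mean_acc - 0.2) < 3 * np.sqrt(0.2 * 0.8 / (50 * 20))

    def test_training_not_worse_than_heldout_on_average(self, labelled_dataset):
        tr_acc, te_acc = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            train = labelled_dataset(gaussian_classes(rng, sep=0.15, noise=0.1))
            test = labelled_dataset(gaussian_classes(rng, n=6, sep=0.15, noise=0.1))
            res = fit_simca(train)
            tr_acc.append(res.accuracy())
            te_acc.append(res.accuracy(test))
        assert np.mean(tr_acc) >= np.mean(te_acc)

    def test_grid_mismatch_raises(self, labelled_dataset):
        rng = np.random.default_rng(0)
        res = fit_simca(labelled_dataset(gaussian_classes(rng, n_classes=2)))
        other = SpectralDataset(np.linspace(900, 1700, 50),
                                rng.normal(size=(1, 50)))
        with pytest.raises(IncompatibleGridError):
            res.classify(other)
        with pytest.raises(IncompatibleGridError):
            res.classify(np.zeros((1, 30)))


class TestDiscriminatingPower:
    def test_flat_near_one_for_identical_classes(self, labelled_dataset):
        rng = np.random.default_rng(5)
        blocks = [(0, rng.normal(0, 0.1, (30, 50))),
                  (1, rng.normal(0, 0.1, (30, 50)))]
        dp = fit_simca(labelled_dataset(blocks)).discriminating_power
        assert abs(np.median(dp) - 1.0) < 0.35
        assert dp.max() / dp.min() < 3.0

    def test_argmax_at_differing_channel(self, labelled_dataset):
        for s in range(10):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 0.05, (15, 50))
            b = rng.normal(0, 0.05, (15, 50))
            b[:, 23] += 1.0
            dp = fit_simca(labelled_dataset([(0, a), (1, b)])).discriminating_power
            assert abs(int(np.argmax(dp)) - 23) <= 1

    def test_scale_invariance(self, labelled_dataset):
        rng = np.random.default_rng(9)
        blocks = gaussian_classes(rng, n_classes=3)
        d1 = fit_simca(labelled_dataset(blocks)).discriminating_power
        doubled = [(c, 2.0 * X) for c, X in blocks]
        d2 = fit_simca(labelled_dataset(doubled)).discriminating_power
        np.testing.assert_allclose(d1, d2, rtol=1e-8)

    def test_peaks_recover_injected_bands(self):
        """Generator-injected class-differential bands must surface as the
        top discriminating-power peaks."""
        from aquaphot.bands import find_peaks

        inject = [1360, 1404, 1459, 1534]
        hits = 0
        for s in range(20):
            traj = {b: [[0, 0.0], [4, 0.08]] for b in inject}
            cfg = SyntheticConfig(
                seed=s, n_days=5, n_fruits=6, n_positions=1, n_replicates=2,
                conditions=("CF",), trajectories={"CF": traj},
                band_centres=tuple(inject), band_base_amplitude=0.0,
                gain_sd=0.0, amp_jitter_sd=0.0,
            )
            ds = crop_region(generate_spectra(cfg), 1300, 1600)
            dp = fit_simca(ds).discriminating_power
            top = sorted(find_peaks(dp), key=lambda t: -t[2])[: len(inject)]
            chans = {c for c, _s, _m in top}
            hits += all(
                any(abs(nearest_channel(ds, b) - c) <= 1 for c in chans)
                for b in inject
            )
        assert hits >= 18


def test_json_round_trip(labelled_dataset):
    rng = np.random.default_rng(3)
    blocks = gaussian_classes(rng, n_classes=3)
    res = fit_simca(labelled_dataset(blocks))
    restored = SIMCAResults.from_json(res.to_json())
    X = np.vstack([b for _, b in blocks])
    np.testing.assert_array_equal(restored.predict(X), res.predict(X))
    np.testing.assert_allclose(
        restored.interclass_distances.to_numpy(),
        res.interclass_distances.to_numpy(),
    )
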
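"""The training algorithm: augmentation, ramps, ensembling, losses, fit."""

import numpy as np
import pytest

from csspm.network import ModelConfig
from csspm.trainer import (
    CsspmClassifier,
    EnsembleState,
    TrainConfig,
    augment,
    consistency_loss,
    fit,
    lr_schedule,
    ramp_up_weight,
    supervised_loss,
    total_loss,
    update_ensemble,
)
from conftest import random_sample_set

RNG = np.random.default_rng


class TestAugment:
    def test_sigma_zero_identity(self):
        x = RNG(0).normal(size=(4, 3))
        assert augment(x, 0.0, RNG(1)) is x

    def test_noise_std_matches_sigma(self):
        """Sample std of (x' - x)/scale over 10^6 draws is 0.15 +- 0.001."""
        x = np.zeros(1_000_000)
        d = augment(x, 0.15, RNG(2), scale=2.0) - x
        assert (d / 2.0).std() == pytest.approx(0.15, abs=0.001)

    def test_noise_zero_mean(self):
        n = 1_000_000
        d = augment(np.zeros(n), 0.15, RNG(3)) - 0.0
        se = 0.15 / np.sqrt(n)
        assert abs(d.mean()) < 3 * se


class TestRampUp:
    def test_plateau_at_tau(self):
        assert ramp_up_weight(30, 30.0, 30.0) == pytest.approx(30.0)

    def test_beyond_tau(self):
        assert ramp_up_weight(45, 30.0, 30.0) == pytest.approx(30.0)

    def test_at_zero(self):
        assert ramp_up_weight(0, 30.0, 30.0) == pytest.approx(30.0 * np.exp(-5))

    def test_continuous_and_nondecreasing(self):
        ts = np.linspace(0, 40, 401)
        w = [ramp_up_weight(t, 30.0, 30.0) for t in ts]
        assert np.all(np.diff(w) >= -1e-12)
        assert ramp_up_weight(30.0 - 1e-9) == pytest.approx(ramp_up_weight(30.0 + 1e-9))


class TestEnsemble:
    def test_first_epoch_bias_correction_exact(self):
        """At t=1 the corrected target equals the prediction itself."""
        st = EnsembleState.initial(3, 2)
        v = RNG(0).random((3, 2))
        st = update_ensemble(st, v, alpha=0.6)
        np.testing.assert_allclose(st.targets, v, atol=1e-12)

    def test_constant_prediction_fixed_point(self):
        st = EnsembleState.initial(2, 2)
        v = np.array([[0.3, 0.7], [0.9, 0.1]])
        for _ in range(7):
            st = update_ensemble(st, v, alpha=0.6)
            np.testing.assert_allclose(st.targets, v, atol=1e-12)

    def test_matches_bruteforce_weighted_sum(self):
        """Corrected target equals (1-a) sum a^(t-s) z_s / (1-a^t)."""
        rng = RNG(4)
        for _ in range(20):
            alpha = rng.uniform(0.05, 0.95)
            zs = rng.random((8, 5, 2))
            st = EnsembleState.initial(5, 2)
            for t, z in enumerate(zs, start=1):
                st = update_ensemble(st, z, alpha)
                ref = sum(alpha ** (t - s) * zs[s - 1] for s in range(1, t + 1))
                ref *= (1 - alpha) / (1 - alpha ** t)
                np.testing.assert_allclose(st.targets, ref, atol=1e-10)

    def test_alpha_to_zero_gives_last_prediction(self):
        st = EnsembleState.initial(2, 2)
        zs = RNG(5).random((4, 2, 2))
        for z in zs:
            st = update_ensemble(st, z, alpha=1e-12)
        np.testing.assert_allclose(st.targets, zs[-1], atol=1e-9)

    def test_targets_are_convex_combinations(self):
        """Each target component lies within [min, max] of past predictions."""
        rng = RNG(6)
        zs = rng.random((10, 4, 2))
        zs /= zs.sum(axis=2, keepdims=True)  # probability vectors
        st = EnsembleState.initial(4, 2)
        for t, z in enumerate(zs, start=1):
            st = update_ensemble(st, z, 0.6)
            past = zs[:t]
            assert np.all(st.targets >= past.min(axis=0) - 1e-12)
            assert np.all(st.targets <= past.max(axis=0) + 1e-12)
        # convex weights sum to one, so targets stay on the simplex
        np.testing.assert_allclose(st.targets.sum(axis=1), 1.0, atol=1e-12)


class TestLosses:
    def test_perfect_predictions_near_zero(self):
        z = np.array([[0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 0])
        loss, _ = supervised_loss(z, y, np.array([True, True]))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_half_confidence_is_ln2(self):
        z = np.array([[0.5, 0.5]])
        loss, _ = supervised_loss(z, np.array([1]), np.array([True]))
        assert loss == pytest.approx(np.log(2), abs=1e-10)

    def test_unlabeled_batch_zero(self):
        z = RNG(0).random((4, 2))
        loss, grad = supervised_loss(z, np.full(4, -1), np.zeros(4, bool))
        assert loss == 0.0
        assert np.all(grad == 0)

    def test_consistency_zero_at_match(self):
        z = RNG(1).random((3, 2))
        loss, _ = consistency_loss(z, z.copy(), 2)
        assert loss == 0.0

    def test_consistency_opposite_onehot(self):
        loss, _ = consistency_loss(np.array([[1.0, 0.0]]),
                                   np.array([[0.0, 1.0]]), 2)
        assert loss == pytest.approx(1.0)

    def test_consistency_duplication_invariant(self):
        z = RNG(2).random((5, 2))
        t = RNG(3).random((5, 2))
        l1, _ = consistency_loss(z, t, 2)
        l2, _ = consistency_loss(np.tile(z, (2, 1)), np.tile(t, (2, 1)), 2)
        assert l1 == pytest.approx(l2)

    def test_total_loss_combinations(self):
        assert total_loss(1.2, 0.5, t=10, omega_max=0.0) == 1.2
        assert total_loss(1.2, 0.5, t=45, omega_max=30.0) == pytest.approx(1.2 + 15.0)
        assert total_loss(1.2, 0.0, t=45) == pytest.approx(1.2)


class TestLrSchedule:
    cfg = TrainConfig()

    def test_flat_before_rampdown(self):
        assert lr_schedule(1, self.cfg) == pytest.approx(5e-4)
        assert lr_schedule(20, self.cfg) == pytest.approx(5e-4)

    def test_final_epoch_value(self):
        assert lr_schedule(50, self.cfg) == pytest.approx(5e-4 * np.exp(-12.5))

    def test_nonincreasing(self):
        lrs = [lr_schedule(t, self.cfg) for t in range(1, 51)]
        assert np.all(np.diff(lrs) <= 1e-15)


class TestFit:
    mc = ModelConfig(n_channels=2)
    tc = TrainConfig(max_epochs=4, ramp_tau=3.0, rampdown_length=2,
                     batch_size=16, seed=1)

    def _data(self, label_frac=1.0, n=40):
        train = random_sample_set(n, seed=10, label_frac=label_frac)
        val = random_sample_set(24, seed=11)
        return train, val

    def test_requires_labeled_samples(self):
        train, val = self._data()
        with pytest.raises(ValueError, match="labeled"):
            fit(train.x, train.y, np.zeros(len(train), bool),
                val.x, val.y, self.mc, self.tc)

    def test_history_and_checkpoint_contract(self):
        train, val = self._data(label_frac=0.5)
        clf = CsspmClassifier.from_sample_sets(train, val, self.mc, self.tc)
        res = clf.fit()
        assert len(res.history) == 4
        accs = [h["val_accuracy"] for h in res.history]
        assert res.best_val_accuracy == max(accs)
        assert res.best_epoch == accs.index(max(accs)) + 1  # earliest on ties
        assert res.ensemble.epoch == 4
        assert np.isfinite([h["loss_sup"] for h in res.history]).all()
        assert "best val accuracy" in res.summary()

    def test_deterministic_given_seed(self):
        train, val = self._data(label_frac=0.5)
        clf = CsspmClassifier.from_sample_sets(train, val, self.mc, self.tc)
        r1, r2 = clf.fit(), clf.fit()
        assert [h["loss_sup"] for h in r1.history] == \
               [h["loss_sup"] for h in r2.history]
        for a, b in zip(r1.weights, r2.weights):
            np.testing.assert_array_equal(a, b)

    def test_learns_separable_toy_task(self):
        train, val = self._data(label_frac=1.0, n=80)
        mc = ModelConfig(n_channels=2, bn_momentum=0.9)  # fast-adapting stats
        tc = TrainConfig(max_epochs=15, ramp_tau=7.0, rampdown_length=3,
                         batch_size=16, seed=2)
        res = CsspmClassifier.from_sample_sets(train, val, mc, tc).fit()
        assert res.best_val_accuracy > 0.8

    def test_validation_must_be_labeled(self):
        train, val = self._data()
        bad = val.as_unlabeled()
        with pytest.raises(ValueError, match="validation"):
            CsspmClassifier.from_sample_sets(train, bad, self.mc, self.tc)
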
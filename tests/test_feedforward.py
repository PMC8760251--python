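"""Feedforward construction: exact gating of null and potent modes."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_toy_activity
from nullspan.feedforward import (ModeMask, build_feedforward,
                                  make_lateral_weights, simulate_receiver)
from nullspan.modes import decompose, mode_correlations, project_modes
from nullspan.rate_network import ActivityMatrix


class TestModeMask:
    def test_from_ranks_and_fraction(self):
        m = ModeMask.from_null_ranks(10, [1, 5])
        assert m.n_null == 2 and m.is_null[0] and m.is_null[4]
        m2 = ModeMask.from_fraction(10, 0.3, seed=0)
        assert m2.n_null == 3
        m3 = ModeMask.from_fraction(10, 0.4, how="tail")
        assert np.array_equal(np.nonzero(m3.is_null)[0], [6, 7, 8, 9])

    def test_bad_ranks_rejected(self):
        with pytest.raises(ValueError):
            ModeMask.from_null_ranks(5, [6])


class TestBuildFeedforward:
    def test_all_potent_acts_as_plain_projection(self, sender_small,
                                                 sender_small_basis):
        mask = ModeMask(np.zeros(20, dtype=bool))
        model = build_feedforward(sender_small, mask, seed=3,
                                  basis=sender_small_basis)
        x = sender_small.rates
        zx = model.random_projection @ x
        assert (np.linalg.norm(model.weights @ x - zx)
                / np.linalg.norm(zx)) < 1e-6

    def test_all_null_silences_everything(self, sender_small,
                                          sender_small_basis):
        mask = ModeMask(np.ones(20, dtype=bool))
        model = build_feedforward(sender_small, mask, seed=3,
                                  basis=sender_small_basis)
        x = sender_small.rates
        assert np.linalg.norm(model.weights @ x) < 1e-6 * np.linalg.norm(x)
        recv = simulate_receiver(model, sender_small)
        assert np.allclose(recv.rates, model.bias, atol=1e-6)

    def test_training_identity_holds(self, sender_small, sender_small_basis):
        """W0 X equals Z X V0 V0^T on the training activity."""
        mask = ModeMask.from_fraction(20, 0.35, seed=9)
        model = build_feedforward(sender_small, mask, seed=9,
                                  basis=sender_small_basis)
        x = sender_small.rates
        v0 = model.masked_eigenvectors
        target = model.random_projection @ x @ v0 @ v0.T
        assert (np.linalg.norm(model.weights @ x - target)
                / np.linalg.norm(target)) < 1e-6

    def test_null_modes_do_not_propagate(self, sender_small,
                                         sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.35, seed=9)
        model = build_feedforward(sender_small, mask, seed=9,
                                  basis=sender_small_basis)
        x = sender_small.rates
        v = sender_small_basis.right_vectors
        norm_wx = np.linalg.norm(model.weights @ x)
        for k in np.nonzero(mask.is_null)[0]:
            comp = x @ np.outer(v[:, k], v[:, k])
            assert np.linalg.norm(model.weights @ comp) <= 1e-6 * norm_wx

    def test_weight_distribution_centered(self, sender_small,
                                          sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.5, seed=4)
        model = build_feedforward(sender_small, mask, seed=4,
                                  basis=sender_small_basis)
        w = model.weights.ravel()
        se = w.std() / np.sqrt(w.size)
        assert abs(w.mean()) < 3 * se

    def test_too_few_time_bins_rejected(self, rng):
        act = ActivityMatrix(rates=rng.normal(size=(10, 10)), dt=1.0)
        with pytest.raises(ValueError, match="time bins"):
            build_feedforward(act, ModeMask(np.zeros(10, dtype=bool)), seed=0)

    def test_mask_length_checked(self, sender_small):
        with pytest.raises(ValueError, match="mask length"):
            build_feedforward(sender_small,
                              ModeMask(np.zeros(5, dtype=bool)), seed=0)


@pytest.fixture(scope="module")
def toy():
    act = make_toy_activity()
    basis = decompose(act)
    mask = ModeMask.from_null_ranks(3, [1])  # top-variance mode null
    model = build_feedforward(act, mask, seed=43, basis=basis)
    return act, basis, model


class TestToyGating:
    """Three-neuron example: one mode silenced, others transmitted."""

    def test_null_mode_drive_is_flat_at_bias(self, toy):
        act, basis, model = toy
        null_drive = project_modes(act, basis, {1}).mode_timeseries
        y = simulate_receiver(
            model, ActivityMatrix(rates=null_drive, dt=act.dt))
        assert np.max(np.abs(y.rates - model.bias)) < 1e-6

    def test_potent_mode_drive_is_structured(self, toy):
        act, basis, model = toy
        potent_drive = project_modes(act, basis, {2}).mode_timeseries
        y = simulate_receiver(
            model, ActivityMatrix(rates=potent_drive, dt=act.dt))
        assert np.ptp(y.rates) > 1e-3

    def test_sender_distribution_similar_across_conditions(self, toy):
        act, basis, _ = toy
        null_drive = project_modes(act, basis, {1}).mode_timeseries
        potent_drive = project_modes(act, basis, {2}).mode_timeseries
        ks = stats.ks_2samp(null_drive.ravel(), potent_drive.ravel())
        assert ks.statistic < 0.2


class TestReceiver:
    def test_zero_weights_give_constant_bias(self, sender_small):
        mask = ModeMask(np.ones(20, dtype=bool))
        model = build_feedforward(sender_small, mask, seed=1)
        recv = simulate_receiver(model, sender_small)
        assert np.allclose(recv.rates, 10.0, atol=1e-6)

    def test_zero_lateral_reduces_to_plain_receiver(self, sender_small,
                                                    sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.5, seed=2)
        model = build_feedforward(sender_small, mask, seed=2,
                                  basis=sender_small_basis)
        model.lateral_weights = np.zeros((20, 20))
        y0 = simulate_receiver(model, sender_small)
        ylat = simulate_receiver(model, sender_small, lateral=True)
        assert np.array_equal(y0.rates, ylat.rates)

    def test_potent_ranks_better_correlated_than_null(self, sender_small,
                                                      sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.5, seed=5)
        model = build_feedforward(sender_small, mask, seed=5,
                                  basis=sender_small_basis)
        for lateral in (False, True):
            if lateral:
                make_lateral_weights(model, seed=6)
            recv = simulate_receiver(model, sender_small, lateral=lateral)
            corr = mode_correlations(sender_small, recv, absolute=True)
            null_idx = np.nonzero(mask.is_null)[0]
            pot_idx = np.nonzero(~mask.is_null)[0]
            assert corr[pot_idx].mean() > corr[null_idx].mean()

    def test_observation_noise_is_seeded(self, sender_small,
                                         sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.5, seed=2)
        model = build_feedforward(sender_small, mask, seed=2,
                                  receiver_noise_sigma2=0.01,
                                  basis=sender_small_basis)
        a = simulate_receiver(model, sender_small, noise_seed=7)
        b = simulate_receiver(model, sender_small, noise_seed=7)
        assert np.array_equal(a.rates, b.rates)

    def test_shape_mismatch_rejected(self, sender_small, rng):
        mask = ModeMask(np.zeros(20, dtype=bool))
        model = build_feedforward(sender_small, mask, seed=0)
        wrong = ActivityMatrix(rates=rng.normal(size=(7, 50)), dt=1.0)
        with pytest.raises(ValueError, match="neurons"):
            simulate_receiver(model, wrong)


class TestLateralWeights:
    def test_range_and_spread_match(self, sender_small, sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.3, seed=8)
        model = build_feedforward(sender_small, mask, seed=8,
                                  basis=sender_small_basis)
        wlat = make_lateral_weights(model, seed=9)
        w0 = model.weights
        assert wlat.min() >= w0.min() and wlat.max() <= w0.max()
        assert abs(wlat.std() - w0.std()) / w0.std() < 0.3

    def test_seeded_reproducibility(self, sender_small, sender_small_basis):
        mask = ModeMask.from_fraction(20, 0.3, seed=8)
        model = build_feedforward(sender_small, mask, seed=8,
                                  basis=sender_small_basis)
        a = make_lateral_weights(model, seed=1)
        b = make_lateral_weights(model, seed=1)
        assert np.array_equal(a, b)

    def test_degenerate_zero_weights(self, sender_small):
        mask = ModeMask(np.ones(20, dtype=bool))
        model = build_feedforward(sender_small, mask, seed=1)
        wlat = make_lateral_weights(model, seed=2)
        assert not wlat.any()
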
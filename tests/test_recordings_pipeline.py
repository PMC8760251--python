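"""End-to-end paired-recordings pipeline on synthetic sessions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nullspan.rate_network import ActivityMatrix
from nullspan.recordings_pipeline import (RecordingSession, SplitAssignment,
                                          area_dimensionality,
                                          bootstrap_null_dominance,
                                          generate_synthetic_session,
                                          split_population,
                                          trial_null_potent)


@pytest.fixture(scope="module")
def small_session():
    return generate_synthetic_session(n_a=40, n_b=12, n_trials=8,
                                      true_null_fraction=0.8, seed=7)


class TestGeneration:
    def test_structure_and_metadata(self, small_session):
        s = small_session
        assert s.n_trials == 8 and s.n_a == 40 and s.n_b == 12
        assert s.area_a[0].n_bins == s.area_b[0].n_bins
        assert s.metadata["true_null_fraction"] == 0.8
        assert len(s.metadata["source_ids"]) == 12

    def test_seeded_reproducibility(self):
        a = generate_synthetic_session(n_a=30, n_b=10, n_trials=2, seed=3)
        b = generate_synthetic_session(n_a=30, n_b=10, n_trials=2, seed=3)
        for ta, tb in zip(a.area_a + a.area_b, b.area_a + b.area_b):
            assert np.array_equal(ta.rates, tb.rates)

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError, match="twice"):
            generate_synthetic_session(n_a=20, n_b=12, n_trials=1, seed=0)

    def test_stimulus_envelope_shape(self, small_session):
        """Population rate rises after onset and relaxes in the blank."""
        mean_rate = small_session.area_a[0].rates.mean(axis=0)
        onset = mean_rate[:50].mean()
        stim = mean_rate[300:1200].mean()
        blank_end = mean_rate[-300:].mean()
        assert stim > onset
        assert blank_end < stim


class TestSplit:
    def test_reference_sizes(self):
        sess = generate_synthetic_session(n_a=111, n_b=37, n_trials=1,
                                          seed=5)
        a = split_population(sess, 37, seed=1)
        assert a.group1_ids.size == a.group2_ids.size == 37
        assert np.intersect1d(a.group1_ids, a.group2_ids).size == 0

    def test_smallest_split(self, small_session):
        a = split_population(small_session, 2, seed=0)
        assert set(a.group1_ids).isdisjoint(a.group2_ids)

    def test_seeded(self, small_session):
        a = split_population(small_session, 12, seed=9)
        b = split_population(small_session, 12, seed=9)
        assert np.array_equal(a.group1_ids, b.group1_ids)

    def test_insufficient_neurons(self, small_session):
        with pytest.raises(ValueError):
            split_population(small_session, 25, seed=0)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SplitAssignment(group1_ids=[0, 1], group2_ids=[1, 2])


class TestTrialAnalysis:
    def test_single_trial_gives_one_row(self):
        sess = generate_synthetic_session(n_a=30, n_b=10, n_trials=1, seed=2)
        table = trial_null_potent(sess, psth_residual=False)
        assert len(table) == 1
        assert {"phi_potent", "phi_null", "ratio_final"} <= set(table.columns)

    @pytest.mark.parametrize("fraction,side", [(0.8, "above"),
                                               (0.2, "below")])
    def test_median_tracks_construction(self, fraction, side):
        sess = generate_synthetic_session(n_a=40, n_b=12, n_trials=8,
                                          true_null_fraction=fraction,
                                          seed=19)
        med = trial_null_potent(sess, psth_residual=False) \
            .ratio_final.median()
        assert (med > 0.5) if side == "above" else (med < 0.5)

    def test_ground_truth_recovery(self):
        """Median per-trial estimate lands within 0.1 of the construction."""
        for truth in (0.2, 0.5, 0.8):
            sess = generate_synthetic_session(
                n_a=111, n_b=37, n_trials=20, true_null_fraction=truth,
                seed=11)
            med = trial_null_potent(sess, psth_residual=False) \
                .ratio_final.median()
            assert abs(med - truth) <= 0.1

    def test_ab_distribution_larger_than_aa(self):
        """A receiver built mostly of null modes shows a larger null
        ratio than the within-area mapping (rank-sum, one-sided)."""
        sess = generate_synthetic_session(n_a=111, n_b=37, n_trials=25,
                                          true_null_fraction=0.8, seed=13)
        ab = trial_null_potent(sess, comparison="AB", seed=1)
        aa = trial_null_potent(sess, comparison="AA", seed=1)
        _, p = stats.mannwhitneyu(ab.ratio_final, aa.ratio_final,
                                  alternative="greater")
        assert p < 0.01

    def test_bad_comparison_rejected(self, small_session):
        with pytest.raises(ValueError):
            trial_null_potent(small_session, comparison="BB")


class TestBootstrap:
    def test_dominance_tracks_truth(self):
        hi = generate_synthetic_session(n_a=40, n_b=12, n_trials=4,
                                        true_null_fraction=0.9, seed=17)
        lo = generate_synthetic_session(n_a=40, n_b=12, n_trials=4,
                                        true_null_fraction=0.1, seed=17)
        assert bootstrap_null_dominance(hi, n_boot=8, seed=3) >= 0.95
        assert bootstrap_null_dominance(lo, n_boot=8, seed=3) <= 0.05

    def test_single_step_deterministic(self, small_session):
        a = bootstrap_null_dominance(small_session, n_boot=1, seed=5)
        b = bootstrap_null_dominance(small_session, n_boot=1, seed=5)
        assert a == b


class TestDimensionality:
    def test_rank_one_area_dominated_by_first_mode(self, rng):
        t = rng.normal(size=400)
        a = [ActivityMatrix(rates=np.outer(rng.normal(size=6), t), dt=1.0)]
        b = [ActivityMatrix(rates=rng.normal(size=(6, 400)), dt=1.0)]
        sess = RecordingSession(area_a=a, area_b=b,
                                trial_metadata=pd.DataFrame({
                                    "trial_index": [0], "stimulus_id": [0]}),
                                bin=1.0)
        table = area_dimensionality(sess)
        first_a = table[(table.area == "A") & (table["rank"] == 1)]
        assert first_a.explained_variance_fraction.iloc[0] > 0.99

    def test_cumulative_curves_reach_unity(self, small_session):
        table = area_dimensionality(small_session)
        for area in ("A", "B"):
            cum = table[table.area == area].cumulative.to_numpy()
            assert np.all(np.diff(cum) >= -1e-12)
            assert cum[-1] == pytest.approx(1.0)

    def test_white_noise_area_fractions_flat(self, rng):
        n = 37
        x = [ActivityMatrix(rates=rng.normal(size=(n, 3000)), dt=1.0)]
        sess = RecordingSession(area_a=x, area_b=x,
                                trial_metadata=pd.DataFrame({
                                    "trial_index": [0], "stimulus_id": [0]}),
                                bin=1.0)
        table = area_dimensionality(sess)
        top = table[table.area == "A"].explained_variance_fraction.max()
        assert top < 2 * 1.5 / n
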
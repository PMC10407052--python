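"""Synthetic-data generators: determinism, planted structure, trial logs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numsense import (
    backbone_accuracy, gen_activation_dataset, gen_category_profiles,
    gen_image_dataset, gen_trial_log, logistic_curve, perf_from_trials,
    population_moments, psychometric, train_mock_backbone,
)
from numsense.config import ConfigError, SynthActivationConfig


class TestCategoryProfiles:
    def test_identity_like_at_full_diag_strength(self):
        prof = gen_category_profiles(5, 8, diag_strength=1.0, seed=0)
        corr = np.corrcoef(prof.values)
        assert np.allclose(np.diag(corr), 1.0)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(off < 1.0)

    def test_argmax_on_diagonal(self):
        prof = gen_category_profiles(10, 50, diag_strength=0.5, seed=4)
        assert np.array_equal(prof.values.argmax(axis=1), np.arange(10))

    def test_rows_distinct_and_bounded(self):
        prof = gen_category_profiles(20, 100, seed=2)
        corr = np.corrcoef(prof.values)
        assert np.all(corr[~np.eye(20, dtype=bool)] < 1.0)
        assert prof.values.min() >= 0 and prof.values.max() <= 1

    def test_pairwise_correlations_match_direct_formula(self, rng):
        prof = gen_category_profiles(20, 100, seed=7)
        v = prof.values
        fast = np.corrcoef(v)
        for i, j in [(0, 1), (3, 17), (10, 10), (5, 19)]:
            a, b = v[i], v[j]
            manual = (((a - a.mean()) * (b - b.mean())).sum()
                      / np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()))
            assert fast[i, j] == pytest.approx(manual, abs=1e-12)

    def test_too_many_categories_errors(self):
        with pytest.raises(ConfigError):
            gen_category_profiles(10, 5)


class TestActivationGenerator:
    def test_seed_determinism(self):
        cfg = SynthActivationConfig(n_units=50, n_pictures_per_group=20, n_increasing=5,
                                    n_decreasing=2, seed=9)
        a = gen_activation_dataset(cfg)
        b = gen_activation_dataset(cfg)
        assert np.array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.meta, b.meta)

    def test_values_nonnegative_and_shape(self, planted_small):
        assert planted_small.values.min() >= 0
        assert planted_small.values.shape == (7 * 200, 100)

    def test_no_planted_effect_groups_exchangeable(self):
        """With zero slope and no variance scaling, group means agree within 3 SE."""
        cfg = SynthActivationConfig(n_units=60, n_pictures_per_group=300,
                                    n_increasing=0, n_decreasing=0,
                                    slope_mean=0.0, sigma_scale=1.0, seed=13)
        acts = gen_activation_dataset(cfg)
        g = acts.groups
        m = np.vstack([acts.values[g == k].mean(axis=0) for k in range(1, 8)])
        s = np.vstack([acts.values[g == k].std(axis=0, ddof=1) for k in range(1, 8)])
        z = (m - m.mean(axis=0)) / (s / np.sqrt(300))
        assert np.mean(np.abs(z) < 3) > 0.99

    def test_planted_increasing_units_rise_between_groups(self):
        """Monte-Carlo check of the generator against its own population means."""
        cfg = SynthActivationConfig(n_units=100, n_pictures_per_group=4000,
                                    n_increasing=10, n_decreasing=0,
                                    slope_mean=0.1, sigma_scale=0.95, seed=3)
        acts = gen_activation_dataset(cfg)
        inc = acts.attrs["increasing_units"]
        g = acts.groups
        m = np.vstack([acts.values[g == k][:, inc].mean(axis=0) for k in range(1, 8)])
        rises = (np.diff(m, axis=0) > 0).mean()
        assert rises >= 0.95

    def test_population_moments_match_samples_within_4_se(self):
        """Effect-size contract: closed-form moments vs sample estimates at n=1000."""
        cfg = SynthActivationConfig(n_units=50, n_pictures_per_group=1000,
                                    n_increasing=8, n_decreasing=4,
                                    slope_mean=0.05, sigma_scale=0.9, seed=17)
        acts = gen_activation_dataset(cfg)
        mom = population_moments(cfg)
        g = acts.groups
        inc = acts.attrs["increasing_units"]
        for k in (1, 4, 7):
            block = acts.values[g == k][:, inc]
            se_mean = mom["inc_std"][k - 1] / np.sqrt(1000)
            assert np.all(np.abs(block.mean(axis=0) - mom["inc_mean"][k - 1]) < 4 * se_mean)
            se_std = mom["inc_std"][k - 1] / np.sqrt(2 * (1000 - 1))
            assert np.all(np.abs(block.std(axis=0, ddof=1) - mom["inc_std"][k - 1]) < 4 * se_std)

    def test_fidelity_controls_profile_correlation(self):
        """Higher embedding fidelity gives higher correlation with the category profile."""
        base = dict(n_units=200, n_pictures_per_group=50, n_increasing=10,
                    n_decreasing=5, n_categories=10, seed=5)
        lo = gen_activation_dataset(SynthActivationConfig(embed_fidelity=0.2, **base))
        hi = gen_activation_dataset(SynthActivationConfig(embed_fidelity=0.8, **base))
        prof = lo.attrs["profiles"]

        def mean_self_corr(acts):
            rs = []
            for row, cat in zip(acts.values, acts.meta["category"]):
                rs.append(np.corrcoef(row, prof.values[cat])[0, 1])
            return np.mean(rs)

        assert mean_self_corr(hi) > mean_self_corr(lo) + 0.2

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="sigma_scale"):
            SynthActivationConfig(sigma_scale=0.0)
        with pytest.raises(ConfigError, match="embed_fidelity"):
            SynthActivationConfig(embed_fidelity=1.5)
        with pytest.raises(ConfigError, match="n_increasing"):
            SynthActivationConfig(n_units=10, n_increasing=8, n_decreasing=8)


class TestImageDatasetAndBackbone:
    def test_single_category_labels(self):
        images, labels = gen_image_dataset(1, 4, seed=0)
        assert set(labels) == {0} and len(images) == 4

    def test_counts_and_format(self):
        images, labels = gen_image_dataset(10, 50, image_size=32, seed=1)
        assert len(images) == 500
        assert all((lab == labels).sum() == 50 for lab in range(10))
        assert all(im.dtype == np.uint8 and im.shape == (32, 32, 3) for im in images)

    def test_image_size_floor(self):
        with pytest.raises(ConfigError):
            gen_image_dataset(2, 2, image_size=16)

    def test_trained_backbone_beats_chance_by_5x(self, backbone):
        images, labels = gen_image_dataset(10, 20, image_size=64, seed=77)
        acc = backbone_accuracy(backbone, images, labels)
        assert acc > 5 * 0.1
        assert acc > 0.5

    def test_untrained_backbone_at_chance(self, random_backbone):
        images, labels = gen_image_dataset(10, 30, image_size=64, seed=78)
        acc = backbone_accuracy(random_backbone, images, labels)
        # binomial 99.9% band around chance = 0.1 at n = 300
        assert abs(acc - 0.1) < 3.3 * np.sqrt(0.1 * 0.9 / 300)

    def test_training_reproducible(self, toy_images):
        images, labels = toy_images
        a = train_mock_backbone(images[:60], labels[:60], epochs=5, seed=8)
        b = train_mock_backbone(images[:60], labels[:60], epochs=5, seed=8)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_degenerate_label_set_errors(self, toy_images):
        images, labels = toy_images
        with pytest.raises(ValueError, match="degenerate"):
            train_mock_backbone(images[:30], labels[:30], epochs=2, seed=0)


class TestTrialLog:
    def test_row_count_matches_design(self):
        log = gen_trial_log({"superior": logistic_curve(), "inferior": logistic_curve(0.5)},
                            n_participants=2, trials_per_cell=50, seed=0)
        assert len(log) == 2 * 7 * 7 * 50 * 2  # participants x cells x trials x conditions
        per_cell = log.groupby(["participant", "condition"]).size()
        assert (per_cell == 4900 / 2).all()

    def test_step_curve_recovers_oracle_matrix(self):
        step = lambda d: 1.0 if d > 0 else (0.0 if d < 0 else 0.5)
        log = gen_trial_log({"all": step}, n_participants=1, trials_per_cell=20, seed=4)
        perf = perf_from_trials(log)[(0, "all")]["matrix"]
        for i, a in enumerate(range(1, 8)):
            for j, b in enumerate(range(1, 8)):
                if a > b:
                    assert perf.values[i, j] == 1.0
                elif a < b:
                    assert perf.values[i, j] == 0.0

    def test_logistic_log_recovery_within_binomial_se(self):
        """Generator and estimator agree: recovered S(d) near the generating curve."""
        curve = logistic_curve(0.8)
        log = gen_trial_log({"c": curve}, n_participants=12, trials_per_cell=33, seed=6)
        perfs = perf_from_trials(log)
        rates = {d: [] for d in range(-6, 7)}
        for key, entry in perfs.items():
            c = psychometric(entry["matrix"])
            for d in range(-6, 7):
                rates[d].append(c.rate_at(d))
        for d in range(-6, 7):
            pooled = np.mean(rates[d])
            n = 12 * 33 * (7 - abs(d))
            se = np.sqrt(max(curve(d) * (1 - curve(d)), 1e-4) / n)
            assert abs(pooled - curve(d)) < 4 * max(se, 1e-3)

    def test_curve_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rates must lie"):
            gen_trial_log({"bad": lambda d: 1.5}, n_participants=1,
                          trials_per_cell=2, seed=0)
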
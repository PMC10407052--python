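"""The two-picture numerosity comparison task and its psychometric analysis.

For every ordered pair of numerosities (a, b) a trial draws one picture from
group a (stimulus A) and one from group b (stimulus B) and reports "A > B"
iff the decoded value of A exceeds that of B (exact ties broken by a seeded
fair coin). The 7x7 table of reported rates collapses onto signed numerical
distance d = a - b, giving the S-shaped psychometric curve whose steepness
around zero expresses the numerical distance effect.

Off-diagonal cells (a, b) and (b, a) share their picture draws and tie-coins
in mirrored form, so S(d) + S(-d) = 1 holds exactly within a single run;
diagonal trials are independent, so S(0) is a genuine binomial sample around
one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from, spawn_seeds

__all__ = [
    "PerformanceMatrix", "PsychCurve", "logistic_curve",
    "run_comparison", "psychometric", "percent_correct",
    "perf_from_trials", "side_bias", "curve_tests", "noise_robustness",
    "TrialLogError",
]


def logistic_curve(slope: float = 0.8) -> Callable[[int], float]:
    """A symmetric logistic psychometric function of signed distance."""
    def curve(d):
        return 1.0 / (1.0 + np.exp(-slope * d))
    return curve


@dataclass
class PerformanceMatrix:
    """7x7 table of reported "A > B" rates with per-cell trial counts."""

    values: np.ndarray
    trials: np.ndarray
    numbers: np.ndarray = field(default_factory=lambda: np.arange(1, 8))
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.trials = np.asarray(self.trials)
        self.numbers = np.asarray(self.numbers)
        n = len(self.numbers)
        if self.values.shape != (n, n) or self.trials.shape != (n, n):
            raise ValueError("performance matrix and trial counts must be square over the numbers")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if np.any(bad & (self.trials > 0)):
            raise ValueError("reported rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.numbers, name="n_A"),
                            columns=pd.Index(self.numbers, name="n_B"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class PsychCurve:
    """Reported-rate S(d) over signed numerical distances -6..6."""

    distances: np.ndarray
    rates: np.ndarray
    counts: np.ndarray
    agent: str = ""
    condition: str = ""

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.array_equal(self.distances, np.arange(self.distances.min(),
                                                        self.distances.max() + 1)):
            raise ValueError("distances must form a contiguous signed range")

    def rate_at(self, d: int) -> float:
        idx = np.flatnonzero(self.distances == d)
        if idx.size == 0:
            raise KeyError(f"distance {d} outside curve domain")
        return float(self.rates[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distances, "rate": self.rates,
                             "n_trials": self.counts})


def percent_correct(curve: PsychCurve) -> np.ndarray:
    """Percent-correct reading of the curve: max(S, 1 - S) at each distance."""
    return np.maximum(curve.rates, 1.0 - curve.rates)


# ---------------------------------------------------------------------------
# running the task on decoded scores
# ---------------------------------------------------------------------------

def run_comparison(scores_by_group: Mapping[int, np.ndarray],
                   trials_per_cell: int = 100, reps: int = 1, seed=0,
                   condition: str = "") -> list[PerformanceMatrix]:
    """Simulate the comparison task from per-picture decoded values.

    ``scores_by_group`` maps each numerosity to the decoded values of its
    picture pool; trials sample pictures with replacement across trials and
    without replacement within a trial. Returns one matrix per repetition,
    each independently seeded.
    """
    numbers = np.array(sorted(scores_by_group))
    pools = {int(g): np.asarray(scores_by_group[g], dtype=float) for g in numbers}
    for g, pool in pools.items():
        if pool.size == 0:
            raise ValueError(f"empty picture pool for numerosity {g}")
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    seeds = spawn_seeds(int(seed), reps)
    out = []
    for r in range(reps):
        rng = rng_from(seeds[r])
        n = len(numbers)
        wins = np.zeros((n, n))
        for i, a in enumerate(numbers):
            for j, b in enumerate(numbers):
                if j < i:
                    continue  # filled by mirroring
                pa, pb = pools[int(a)], pools[int(b)]
                if i == j:
                    # within-trial draw without replacement when the pool allows
                    hits = 0
                    for _ in range(trials_per_cell):
                        if pa.size >= 2:
                            ia, ib = rng.choice(pa.size, 2, replace=False)
                        else:
                            ia = ib = 0
                        hits += _judge(pa[ia], pa[ib], rng)
                    wins[i, j] = hits
                else:
                    hits = 0
                    for _ in range(trials_per_cell):
                        ia = rng.integers(pa.size)
                        ib = rng.integers(pb.size)
                        hits += _judge(pa[ia], pb[ib], rng)
                    wins[i, j] = hits
                    wins[j, i] = trials_per_cell - hits  # mirrored trials
        out.append(PerformanceMatrix(values=wins / trials_per_cell,
                                     trials=np.full((n, n), trials_per_cell),
                                     numbers=numbers, condition=condition, replicate=r))
    return out


def _judge(score_a: float, score_b: float, rng) -> int:
    if score_a > score_b:
        return 1
    if score_a < score_b:
        return 0
    return int(rng.random() < 0.5)  # seeded fair coin on exact ties


def psychometric(perf: PerformanceMatrix, agent: str = "") -> PsychCurve:
    """Collapse a performance matrix onto signed numerical distance.

    S(d) is the trial-weighted mean over the cells with a - b = d, so the
    result does not depend on any ordering of the cells.
    """
    n = len(perf.numbers)
    dmax = n - 1
    distances = np.arange(-dmax, dmax + 1)
    rates = np.zeros_like(distances, dtype=float)
    counts = np.zeros_like(distances)
    for k, d in enumerate(distances):
        cells = [(i, j) for i in range(n) for j in range(n)
                 if perf.numbers[i] - perf.numbers[j] == d]
        t = np.array([perf.trials[i, j] for i, j in cells], dtype=float)
        v = np.array([perf.values[i, j] for i, j in cells])
        counts[k] = t.sum()
        rates[k] = float((v * t).sum() / t.sum()) if t.sum() else np.nan
    return PsychCurve(distances=distances, rates=rates, counts=counts,
                      agent=agent, condition=perf.condition)


# ---------------------------------------------------------------------------
# human trial logs
# ---------------------------------------------------------------------------

class TrialLogError(ValueError):
    """Raised with a row-level report when a trial log is malformed."""

    def __init__(self, problems: pd.DataFrame):
        self.problems = problems
        super().__init__(
            f"{len(problems)} malformed trial-log row(s); see .problems "
            f"(first offender: row {problems.index[0]}: {problems.iloc[0]['reason']})")


def _validate_log(log: pd.DataFrame, numbers) -> pd.DataFrame:
    required = {"participant", "n_left", "n_right", "response"}
    missing_cols = required - set(log.columns)
    if missing_cols:
        raise TrialLogError(pd.DataFrame(
            {"reason": [f"missing column(s): {sorted(missing_cols)}"]}))
    lo, hi = min(numbers), max(numbers)
    problems = []
    bad_n = ~log["n_left"].isin(numbers) | ~log["n_right"].isin(numbers)
    for idx in log.index[bad_n]:
        problems.append((idx, f"numerosity outside [{lo}, {hi}]"))
    answered = log["response"].notna()
    bad_resp = answered & ~log["response"].isin(["left", "right"])
    for idx in log.index[bad_resp]:
        problems.append((idx, f"response {log.loc[idx, 'response']!r} not in left/right"))
    if problems:
        idx, reasons = zip(*problems)
        raise TrialLogError(pd.DataFrame({"reason": reasons}, index=list(idx)))
    return log


def perf_from_trials(log: pd.DataFrame, numbers: Sequence[int] = range(1, 8),
                     ) -> dict[tuple, dict]:
    """Build per-participant, per-condition performance matrices from a log.

    Convention: cell (a, b) pools the trials with a on the left and b on the
    right and reports the fraction answered "left"; side counterbalancing in
    the log makes this equivalent to the sample/test reading for any curve
    with S(d) + S(-d) = 1. Trials without a response are excluded and
    counted. Malformed rows raise :class:`TrialLogError` with a row report.
    """
    numbers = list(numbers)
    log = _validate_log(log, numbers)
    if "condition" not in log.columns:
        log = log.assign(condition="all")
    out = {}
    for (part, cond), block in log.groupby(["participant", "condition"]):
        answered = block[block["response"].notna()]
        n = len(numbers)
        wins = np.zeros((n, n))
        counts = np.zeros((n, n), dtype=int)
        grouped = answered.groupby(["n_left", "n_right"])["response"]
        for (a, b), resp in grouped:
            i, j = numbers.index(a), numbers.index(b)
            counts[i, j] = len(resp)
            wins[i, j] = (resp == "left").sum()
        with np.errstate(invalid="ignore"):
            values = np.where(counts > 0, wins / np.maximum(counts, 1), np.nan)
        out[(part, cond)] = {
            "matrix": PerformanceMatrix(values=values, trials=counts,
                                        numbers=np.array(numbers), condition=str(cond)),
            "n_missing": int(len(block) - len(answered)),
        }
    return out


def side_bias(log: pd.DataFrame, lo: float = 0.35, hi: float = 0.65) -> pd.DataFrame:
    """Per-participant left-response rate with an exclusion flag.

    Participants answering "left" outside [lo, hi] of trials show a strong
    side bias; the thresholds are configurable and reported, not enforced.
    """
    rows = []
    for part, block in log.groupby("participant"):
        answered = block[block["response"].notna()]
        rate = float((answered["response"] == "left").mean())
        rows.append({"participant": part, "left_rate": rate,
                     "biased": not (lo <= rate <= hi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics on curves
# ---------------------------------------------------------------------------

def curve_tests(curves: Sequence[PsychCurve], baseline: float = 0.5,
                other: Sequence[PsychCurve] | None = None) -> pd.DataFrame:
    """Per-distance tests over replicates or participants.

    One-sample t-test of S(d) against the chance baseline and, when a second
    condition is supplied, a paired t-test between conditions at each
    distance. Raw and Bonferroni-corrected p-values are both reported.
    """
    if len(curves) < 2:
        raise ValueError("tests need >= 2 replicates or participants")
    if other is not None and len(other) != len(curves):
        raise ValueError("paired comparison needs equally many curves per condition")
    distances = curves[0].distances
    mat = np.vstack([c.rates for c in curves])
    rows = []
    n_tests = len(distances)
    for k, d in enumerate(distances):
        x = mat[:, k]
        if np.allclose(x, baseline):
            t1, p1 = 0.0, 1.0
        else:
            t1, p1 = stats.ttest_1samp(x, baseline)
        row = {"distance": int(d), "mean_rate": float(x.mean()),
               "t_vs_chance": float(t1), "p_vs_chance": float(p1),
               "p_vs_chance_bonf": float(min(1.0, p1 * n_tests))}
        if other is not None:
            y = np.vstack([c.rates for c in other])[:, k]
            if np.allclose(x, y):
                t2, p2 = 0.0, 1.0
            else:
                t2, p2 = stats.ttest_rel(x, y)
            row.update({"mean_rate_other": float(y.mean()),
                        "t_paired": float(t2), "p_paired": float(p2),
                        "p_paired_bonf": float(min(1.0, p2 * n_tests))})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# noise robustness sweep (full image pipeline)
# ---------------------------------------------------------------------------

def noise_robustness(model, backbone, scenes_by_group: Mapping[int, Sequence[np.ndarray]],
                     weights: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 3.0),
                     trials_per_cell: int = 100, reps: int = 1, seed=0,
                     ) -> dict[float, PsychCurve]:
    """Psychometric curves after overlaying white noise at several weights.

    For each weight the whole chain runs again: noise overlay, activation
    extraction, normalization, decoding, comparison. The per-image noise
    fields and the comparison trial seeds are shared across weights, so the
    sweep is a paired design and the weight-0 curve reproduces the clean run
    exactly.
    """
    from .activations import extract, normalize_unit_range
    from .stimuli import add_noise

    weights = list(weights)
    if any(w < 0 for w in weights):
        raise ValueError("noise weights must be >= 0")
    noise_seed, cmp_seed = spawn_seeds(int(seed), 2)
    curves = {}
    for w in weights:
        pools = {}
        for g, scenes in scenes_by_group.items():
            imgs = []
            for k, img in enumerate(scenes):
                if w == 0:
                    imgs.append(np.asarray(img))
                else:
                    stim = add_noise(img, w, seed=noise_seed + 7919 * k)
                    imgs.append(stim.pixels)
            acts = normalize_unit_range(extract(backbone, imgs, layer="classifier"))
            pools[int(g)] = decode(model, acts) if not hasattr(model, "decode") \
                else model.decode(acts)
        perfs = run_comparison(pools, trials_per_cell=trials_per_cell, reps=reps,
                               seed=cmp_seed, condition=f"noise{w:g}")
        curve_mat = np.mean([psychometric(p).rates for p in perfs], axis=0)
        template = psychometric(perfs[0])
        curves[float(w)] = PsychCurve(distances=template.distances, rates=curve_mat,
                                      counts=template.counts * reps,
                                      agent="decoder", condition=f"noise{w:g}")
    return curves


from .decoder import decode  # noqa: E402  (placed late to avoid import cycle)
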
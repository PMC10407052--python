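"""Group-coding pattern statistics.

For each numerosity group the per-unit mean and standard deviation across
pictures are computed; the signature of group coding is that the upper decile
of the means rises with the number of items while the lower decile of the
standard deviations falls. A resampling protocol (draw 500 pictures per
group, repeat 10 times) supplies error bars, and one-way ANOVA across groups
(units as observations) with Bonferroni-corrected paired post-hocs supplies
the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_from, spawn_seeds
from .activations import ActivationMatrix

__all__ = ["GroupSummary", "group_summary", "decile_stats", "resample_summary",
           "trend_tests", "HIGH_ACTIVATION_THRESHOLD"]

HIGH_ACTIVATION_THRESHOLD = 0.7


@dataclass
class GroupSummary:
    """Per-group, per-unit response moments across sampled pictures."""

    groups: np.ndarray            # sorted group labels, shape (G,)
    means: np.ndarray             # (G, n_units) per-unit cross-picture mean
    stds: np.ndarray              # (G, n_units) sample std (ddof=1)
    n_pictures: np.ndarray        # (G,) sample size per group
    replicate: int = 0
    with_replacement: bool = False

    def mean_decile90(self) -> np.ndarray:
        """90th percentile of the per-unit means, one value per group."""
        return np.percentile(self.means, 90, axis=1)

    def std_decile10(self) -> np.ndarray:
        """10th percentile of the per-unit standard deviations per group."""
        return np.percentile(self.stds, 10, axis=1)

    def high_count(self, threshold: float = HIGH_ACTIVATION_THRESHOLD) -> np.ndarray:
        """Number of units whose group mean exceeds ``threshold``."""
        return (self.means > threshold).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.groups,
            "n_pictures": self.n_pictures,
            "mean_decile90": self.mean_decile90(),
            "std_decile10": self.std_decile10(),
            "high_count": self.high_count(),
            "replicate": self.replicate,
        })


def group_summary(acts: ActivationMatrix, groups=None, replicate: int = 0) -> GroupSummary:
    """Exact per-unit mean and sample std (ddof=1) for each numerosity group."""
    labels = acts.groups if groups is None else np.asarray(groups)
    uniq = np.unique(labels)
    means, stds, counts = [], [], []
    for g in uniq:
        block = acts.values[labels == g]
        if block.shape[0] < 2:
            raise ValueError(f"group {g} has {block.shape[0]} picture(s); "
                             "need >= 2 for a standard deviation")
        means.append(block.mean(axis=0))
        stds.append(block.std(axis=0, ddof=1))
        counts.append(block.shape[0])
    return GroupSummary(groups=uniq, means=np.vstack(means), stds=np.vstack(stds),
                        n_pictures=np.asarray(counts), replicate=replicate)


def decile_stats(summary: GroupSummary, which: str) -> np.ndarray:
    """Scalar decile summary per group.

    ``mean90``: 90th percentile of the per-unit means; ``std10``: 10th
    percentile of the per-unit standard deviations. Percentiles use linear
    interpolation between order statistics (so unit means 1..100 give a
    mean90 of 90.1).
    """
    if which == "mean90":
        return summary.mean_decile90()
    if which == "std10":
        return summary.std_decile10()
    raise ValueError(f"unknown decile statistic {which!r}; use 'mean90' or 'std10'")


def resample_summary(acts: ActivationMatrix, n_pick: int = 500, reps: int = 10,
                     seed=0) -> list[GroupSummary]:
    """Repeatedly summarize random draws of ``n_pick`` pictures per group.

    Draws are without replacement when the pool allows it, otherwise with
    replacement (flagged on the summary). Each repetition is independently
    seeded from ``seed`` and retained so error bars can be computed.
    """
    labels = acts.groups
    uniq = np.unique(labels)
    seeds = spawn_seeds(int(seed), reps)
    out = []
    for r in range(reps):
        rng = rng_from(seeds[r])
        idx_parts, flagged = [], False
        for g in uniq:
            pool = np.flatnonzero(labels == g)
            replace = pool.size < n_pick
            flagged = flagged or replace
            idx_parts.append(rng.choice(pool, size=min(n_pick, pool.size) if not replace
                                        else n_pick, replace=replace))
        sub = acts.subset(np.concatenate(idx_parts))
        summ = group_summary(sub, replicate=r)
        summ.with_replacement = flagged
        out.append(summ)
    return out


def _pairwise_paired_t(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Paired t-tests between all group pairs over units, Bonferroni-corrected."""
    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        a, b = values[i], values[j]
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_rel(a, b)
        rows.append({"group_a": groups[i], "group_b": groups[j],
                     "t": float(t), "p_raw": float(p),
                     "p_bonferroni": float(min(1.0, p * len(pairs)))})
    return pd.DataFrame(rows)


def trend_tests(summary: GroupSummary) -> dict:
    """One-way ANOVA of per-unit means and stds across numerosity groups.

    The observations are units (so with 1000 units and 7 groups the test has
    6 and 6993 degrees of freedom); post-hoc comparisons pair the same units
    across two groups. Degenerate (zero-variance) inputs are flagged instead
    of producing NaNs. The report round-trips to CSV via the two DataFrames
    it contains.
    """
    if len(summary.groups) < 2:
        raise ValueError("need at least 2 groups for a trend test")
    report = {}
    for name, values in (("mean", summary.means), ("std", summary.stds)):
        degenerate = bool(np.allclose(values, values[0]))
        if degenerate:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*values)
        k, n = values.shape[0], values.size
        report[name] = {
            "F": float(f), "p": float(p),
            "df_between": k - 1, "df_within": n - k,
            "degenerate": degenerate,
        }
        report[f"{name}_posthoc"] = _pairwise_paired_t(values, summary.groups)
    report["anova"] = pd.DataFrame(
        [{"statistic": name, **{k: v for k, v in report[name].items()}}
         for name in ("mean", "std")])
    return report
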
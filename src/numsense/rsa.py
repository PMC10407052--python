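"""Representational similarity analysis across cognitive agents.

Condition-level RSMs are built from the superior/inferior psychometric
curves; picture-wise RSMs come from pairwise win-rate profiles within one
numerosity. Agreement between a candidate agent and a set of reference
agents (12 participants, or 12 repeated network runs standing in for
participants) is the Spearman correlation of RSM upper triangles, tested
with a one-sided Wilcoxon signed-rank across references and controlled for
false discovery rate across candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison import PsychCurve

__all__ = ["RSM", "rsm_from_curves", "rsm_picturewise", "compare_rsms"]


@dataclass
class RSM:
    """Square symmetric dissimilarity matrix with item ids."""

    values: np.ndarray
    ids: list
    agent: str = ""
    level: str = "condition"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.ids) != n:
            raise ValueError("RSM must be square with one id per row")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RSM entries must be finite")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("RSM must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("RSM diagonal must be zero (dissimilarity form)")

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, agent="", level="condition") -> "RSM":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(float), ids=list(df.index), agent=agent, level=level)


def _fold_block(curve: PsychCurve, numbers) -> np.ndarray:
    """7x7 discriminability block: cell (i, j) = folded |S(i - j) - 0.5|.

    Off-diagonal cells average the two signed readings so the block is
    symmetric even when sampling noise breaks S(d) + S(-d) = 1; the diagonal
    is zero by definition (a numerosity is not dissimilar from itself).
    """
    n = len(numbers)
    block = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = numbers[i] - numbers[j]
            block[i, j] = 0.5 * (abs(curve.rate_at(d) - 0.5)
                                 + abs(curve.rate_at(-d) - 0.5))
    return block


def rsm_from_curves(curve_superior: PsychCurve, curve_inferior: PsychCurve,
                    agent: str = "", method: str = "fold",
                    numbers=range(1, 8)) -> RSM:
    """Condition-level RSM from the two embedding-condition S-curves.

    ``method='fold'`` (default): each condition becomes a 7x7 block whose
    (i, j) cell is the folded discriminability |S(i-j) - 0.5| between
    numerosities i and j; the full 14x14 RSM carries the two condition
    blocks on its diagonal and the conditions' mean discriminability in the
    cross-condition cells. ``method='concat'``: the alternative construction
    — the two 13-point curves are concatenated into one vector and the RSM
    is the absolute difference between its entries.
    """
    numbers = list(numbers)
    need = range(-(len(numbers) - 1), len(numbers))
    for c in (curve_superior, curve_inferior):
        missing = [d for d in need if d not in c.distances]
        if missing:
            raise ValueError(f"curve lacks distances {missing}")
    if method == "fold":
        b_sup = _fold_block(curve_superior, numbers)
        b_inf = _fold_block(curve_inferior, numbers)
        n = len(numbers)
        values = np.zeros((2 * n, 2 * n))
        values[:n, :n] = b_sup
        values[n:, n:] = b_inf
        # cross-condition cells: the conditions' mean discriminability at that
        # distance (constant blocks would inject common structure into every
        # agent's RSM and bias the permutation null)
        cross = 0.5 * (b_sup + b_inf)
        values[:n, n:] = cross
        values[n:, :n] = cross.T
        ids = [f"sup:{k}" for k in numbers] + [f"inf:{k}" for k in numbers]
        return RSM(values=values, ids=ids, agent=agent, level="condition")
    if method == "concat":
        v = np.concatenate([curve_superior.rates, curve_inferior.rates])
        values = np.abs(v[:, None] - v[None, :])
        ids = ([f"sup:d{int(d)}" for d in curve_superior.distances]
               + [f"inf:d{int(d)}" for d in curve_inferior.distances])
        return RSM(values=values, ids=ids, agent=agent, level="condition")
    raise ValueError(f"unknown method {method!r}; use 'fold' or 'concat'")


def rsm_picturewise(winrates: np.ndarray, ids=None, agent: str = "") -> RSM:
    """Picture-wise RSM from a pairwise win-rate table within one numerosity.

    Row i of ``winrates`` is picture i's response profile: the rate at which
    it was judged more numerous than every other picture. Dissimilarity is
    1 - Pearson correlation of two profiles with the entries involving
    either picture excluded. Constant profiles make the correlation
    undefined and raise, naming the offending picture.
    """
    W = np.asarray(winrates, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("win-rate table must be square")
    if ids is None:
        ids = list(range(n))
    values = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        keep = np.ones(n, dtype=bool)
        keep[[i, j]] = False
        a, b = W[i, keep], W[j, keep]
        if np.std(a) < 1e-12 or np.std(b) < 1e-12:
            offender = ids[i] if np.std(a) < 1e-12 else ids[j]
            raise ValueError(f"constant response profile for picture {offender}: "
                             "correlation undefined")
        r = float(np.corrcoef(a, b)[0, 1])
        values[i, j] = values[j, i] = 1.0 - r
    return RSM(values=values, ids=list(ids), agent=agent, level="picturewise")


def _spearman_upper(a: RSM, b: RSM) -> float:
    rho = stats.spearmanr(a.upper(), b.upper()).statistic
    return float(rho)


def compare_rsms(references: list[RSM], candidates: list[RSM],
                 min_references: int = 12, alpha: float = 0.05) -> dict:
    """Test each candidate RSM against a reference set.

    Per candidate: Spearman correlation of upper triangles with every
    reference, a one-sided Wilcoxon signed-rank test that those correlations
    exceed zero, and pairwise candidate-vs-candidate signed-rank tests on the
    paired correlation vectors. All p-values are FDR-adjusted
    (Benjamini-Hochberg) jointly; candidates are ranked by mean correlation.
    """
    if len(references) < min_references:
        raise ValueError(f"need >= {min_references} reference RSMs, got {len(references)}")
    shape = references[0].values.shape
    for r in references + candidates:
        if r.values.shape != shape:
            raise ValueError(f"RSM shape mismatch: {r.agent or '?'} has {r.values.shape}, "
                             f"references have {shape}")
    corrs = {c.agent or f"candidate{k}": np.array([_spearman_upper(c, ref)
                                                   for ref in references])
             for k, c in enumerate(candidates)}

    rows, pvals = [], []
    for name, rho in corrs.items():
        if np.allclose(rho, 0):
            w_p = 1.0
        else:
            w_p = float(stats.wilcoxon(rho, alternative="greater").pvalue)
        rows.append({"candidate": name, "mean_correlation": float(rho.mean()),
                     "p_raw": w_p})
        pvals.append(w_p)

    pair_rows = []
    names = list(corrs)
    for a, b in combinations(names, 2):
        diff = corrs[a] - corrs[b]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(corrs[a], corrs[b]).pvalue)
        pair_rows.append({"candidate_a": a, "candidate_b": b, "p_raw": p})
        pvals.append(p)

    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for k, row in enumerate(rows):
        row["p_fdr"] = float(p_adj[k])
        row["significant"] = bool(p_adj[k] < alpha)
    for k, row in enumerate(pair_rows):
        row["p_fdr"] = float(p_adj[len(rows) + k])
        row["significant"] = bool(p_adj[len(rows) + k] < alpha)

    table = (pd.DataFrame(rows)
             .sort_values("mean_correlation", ascending=False)
             .reset_index(drop=True))
    table["rank"] = np.arange(1, len(table) + 1)
    return {"candidates": table, "pairwise": pd.DataFrame(pair_rows),
            "correlations": {k: v.tolist() for k, v in corrs.items()},
            "alpha": alpha}
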
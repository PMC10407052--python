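"""Monotone-unit selection and the numerosity read-out network.

A classifier unit is *increasing* when its mean activation rises strictly
with every step of the numerosity group sequence and every consecutive-group
difference passes a two-sample test at the screening alpha (0.1 by default);
*decreasing* is defined symmetrically. The activations of the selected units
feed a deliberately simple regressor — one fully connected hidden layer
(2000 units by default) and a single linear output whose response is the
estimated number of objects. Mean-squared-error training naturally yields
the compressive bias seen in perception: overestimation of small counts and
underestimation of large ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .activations import ActivationMatrix
from .config import DecoderConfig

__all__ = ["UnitSet", "DecoderModel", "select_monotone_units", "train_decoder", "decode"]


@dataclass
class UnitSet:
    """Indices of monotonically increasing / decreasing classifier units."""

    increasing: np.ndarray
    decreasing: np.ndarray
    alpha: float = 0.1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.increasing = np.asarray(self.increasing, dtype=int)
        self.decreasing = np.asarray(self.decreasing, dtype=int)
        if np.intersect1d(self.increasing, self.decreasing).size:
            raise ValueError("a unit cannot be both increasing and decreasing")

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.increasing, self.decreasing])

    def __len__(self) -> int:
        return self.increasing.size + self.decreasing.size

    @classmethod
    def full(cls, n_units: int, provenance: dict | None = None) -> "UnitSet":
        """The whole layer as the read-out input.

        The monotone screening has a hit rate of a few percent of units at
        full scale, so a desk-scale classifier layer that is only tens of
        units wide is expected to yield zero selected units; analyses on
        such layers read out from the full layer instead, which subsumes
        any screened subset.
        """
        return cls(increasing=np.arange(n_units), decreasing=np.array([], dtype=int),
                   alpha=1.0, provenance=provenance or {"selection": "full-layer"})


def _consecutive_welch_p(acts_by_group: list[np.ndarray]) -> np.ndarray:
    """Two-sided Welch p-values per unit for every consecutive group pair."""
    ps = []
    for a, b in zip(acts_by_group[:-1], acts_by_group[1:]):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        ps.append(p)
    return np.vstack(ps)  # (G-1, n_units)


def select_monotone_units(acts: ActivationMatrix, alpha: float = 0.1,
                          expected_groups=range(1, 8)) -> UnitSet:
    """Screen units whose activation ramps monotonically with numerosity.

    A unit qualifies as increasing iff its group means are strictly
    increasing across the full group sequence AND each consecutive-pair
    Welch two-sample test (across pictures) has p < alpha; decreasing is the
    mirror criterion. No multiple-testing correction is applied — the alpha
    is a screening threshold, not an inference level.
    """
    groups = acts.groups
    present = np.unique(groups)
    missing = [g for g in expected_groups if g not in present]
    if missing:
        raise ValueError(f"missing numerosity group(s) {missing}; "
                         f"groups present: {present.tolist()}")
    blocks = []
    for g in sorted(expected_groups):
        block = acts.values[groups == g]
        if block.shape[0] < 2:
            raise ValueError(f"group {g} needs >= 2 pictures for the pair tests")
        blocks.append(block)
    means = np.vstack([b.mean(axis=0) for b in blocks])   # (G, n_units)
    diffs = np.diff(means, axis=0)
    pvals = _consecutive_welch_p(blocks)
    sig = pvals < alpha
    inc = np.flatnonzero(np.all(diffs > 0, axis=0) & np.all(sig, axis=0))
    dec = np.flatnonzero(np.all(diffs < 0, axis=0) & np.all(sig, axis=0))
    return UnitSet(increasing=inc, decreasing=dec, alpha=alpha,
                   provenance={"layer": acts.layer, "n_units": acts.n_units,
                               "groups": [int(g) for g in sorted(expected_groups)]})


@dataclass
class DecoderModel:
    """Trained read-out: selected units -> hidden layer -> one output unit."""

    unitset: UnitSet
    config: DecoderConfig
    _mlp: object = None

    @property
    def history(self) -> list[float]:
        return list(getattr(self._mlp, "loss_curve_", []))

    @property
    def input_width(self) -> int:
        return len(self.unitset)

    def decode(self, acts: ActivationMatrix) -> np.ndarray:
        return decode(self, acts)

    # -- portable binary + JSON architecture descriptor --------------------
    def save(self, path) -> None:
        from dataclasses import asdict
        path = Path(path)
        mlp = self._mlp
        np.savez_compressed(
            path.with_suffix(".npz"),
            W1=mlp.coefs_[0], b1=mlp.intercepts_[0],
            W2=mlp.coefs_[1], b2=mlp.intercepts_[1],
            increasing=self.unitset.increasing, decreasing=self.unitset.decreasing,
            loss_curve=np.asarray(self.history))
        desc = {"architecture": [self.input_width, self.config.hidden, 1],
                "config": asdict(self.config), "alpha": self.unitset.alpha,
                "provenance": self.unitset.provenance}
        path.with_suffix(".json").write_text(json.dumps(desc))

    @classmethod
    def load(cls, path) -> "DecoderModel":
        from sklearn.neural_network import MLPRegressor
        path = Path(path)
        arr = np.load(path.with_suffix(".npz"))
        desc = json.loads(path.with_suffix(".json").read_text())
        cfg = DecoderConfig(**desc["config"])
        unitset = UnitSet(increasing=arr["increasing"], decreasing=arr["decreasing"],
                          alpha=desc["alpha"], provenance=desc.get("provenance", {}))
        mlp = MLPRegressor(hidden_layer_sizes=(cfg.hidden,))
        # rebuild the fitted state
        mlp.coefs_ = [arr["W1"], arr["W2"]]
        mlp.intercepts_ = [arr["b1"], arr["b2"]]
        mlp.n_layers_ = 3
        mlp.n_outputs_ = 1
        mlp.out_activation_ = "identity"
        mlp.activation = "relu"
        mlp.loss_curve_ = arr["loss_curve"].tolist()
        return cls(unitset=unitset, config=cfg, _mlp=mlp)


def train_decoder(acts: ActivationMatrix, unitset: UnitSet, targets=None,
                  cfg: DecoderConfig | None = None) -> DecoderModel:
    """Fit the read-out network on the selected units' activations.

    ``targets`` defaults to the numerosity group labels. Training minimizes
    squared error with an adaptive first-order optimizer (adam, lr 1e-3, at
    most ``max_epochs`` epochs) and, by default, stops early on a seeded 10%
    validation split when the validation score plateaus.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.neural_network import MLPRegressor

    if len(unitset) == 0:
        raise ValueError("no informative units: the unit set is empty")
    cfg = cfg or DecoderConfig()
    y = np.asarray(acts.groups if targets is None else targets, dtype=float)
    X = acts.values[:, unitset.indices]
    mlp = MLPRegressor(
        hidden_layer_sizes=(cfg.hidden,), activation="relu", solver="adam",
        learning_rate_init=cfg.learning_rate, max_iter=cfg.max_epochs,
        batch_size=min(cfg.batch_size, X.shape[0]),
        early_stopping=cfg.early_stopping, validation_fraction=cfg.validation_fraction,
        n_iter_no_change=cfg.n_iter_no_change, tol=cfg.tol,
        random_state=cfg.seed % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)
    return DecoderModel(unitset=unitset, config=cfg, _mlp=mlp)


def decode(model: DecoderModel, acts: ActivationMatrix | np.ndarray) -> np.ndarray:
    """Per-picture real-valued numerosity estimates (deterministic)."""
    values = acts.values if isinstance(acts, ActivationMatrix) else np.asarray(acts)
    needed = int(model.unitset.indices.max(), ) + 1 if len(model.unitset) else 0
    if values.shape[1] < needed:
        raise ValueError(
            f"activation table has {values.shape[1]} units but the model's unit set "
            f"references index {needed - 1}")
    X = values[:, model.unitset.indices]
    return np.asarray(model._mlp.predict(X), dtype=float)
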
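"""Layer responses: extraction, per-picture normalization, category profiles.

The central container is :class:`ActivationMatrix`, a pictures-by-units table
with per-picture metadata (numerosity group, picture id, variant, ...).
Responses are normalized per picture to [0, 1] using the minimum and maximum
across units of that picture, which is what makes co-activation "sidebands"
comparable between pictures with different absolute response levels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "Backbone", "ActivationMatrix", "CategoryProfileMatrix",
    "extract", "normalize_unit_range", "category_profile_matrix",
]


@runtime_checkable
class Backbone(Protocol):
    """Contract a backbone must satisfy: named layers and a forward pass.

    ``respond`` must be deterministic (evaluation mode) and return one row
    per image with the layer's full (flattened) width.
    """

    identifier: str
    trained: bool

    @property
    def layers(self) -> dict[str, int]:
        """Mapping layer name -> flattened width (e.g. classifier, last_conv)."""
        ...

    def respond(self, images: Sequence[np.ndarray], layer: str) -> np.ndarray:
        ...


@dataclass
class ActivationMatrix:
    """Pictures x units response table plus row metadata.

    ``meta`` is a DataFrame aligned with the rows of ``values``; it always
    carries ``picture_id`` and ``group`` and may carry extras (category,
    fidelity, variant). ``degenerate`` flags rows that had zero range at
    normalization time and were set to all-zero rather than dropped, keeping
    picture counts stable for downstream tasks.
    """

    values: np.ndarray
    meta: pd.DataFrame
    layer: str = "classifier"
    normalized: bool = False
    degenerate: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activation values must be a 2-D pictures x units array")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError(
                f"metadata has {len(self.meta)} rows but values has {self.values.shape[0]}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_pictures(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> np.ndarray:
        return self.meta["group"].to_numpy()

    def subset(self, mask) -> "ActivationMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return ActivationMatrix(
            values=self.values[idx],
            meta=self.meta.iloc[idx],
            layer=self.layer,
            normalized=self.normalized,
            degenerate=None if self.degenerate is None else self.degenerate[idx],
            attrs=dict(self.attrs),
        )

    def by_group(self) -> dict[int, "ActivationMatrix"]:
        return {int(g): self.subset(self.groups == g) for g in np.unique(self.groups)}

    # -- round-trip I/O ----------------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.concat(
            [self.meta.reset_index(drop=True),
             pd.DataFrame(self.values, columns=[f"u{i}" for i in range(self.n_units)])],
            axis=1)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layer="classifier", normalized=False) -> "ActivationMatrix":
        df = pd.read_csv(path)
        unit_cols = [c for c in df.columns if c.startswith("u") and c[1:].isdigit()]
        meta = df.drop(columns=unit_cols)
        return cls(values=df[unit_cols].to_numpy(float), meta=meta,
                   layer=layer, normalized=normalized)

    def save(self, path) -> None:
        """Compact binary container (.npz) with a JSON metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values,
                            degenerate=(np.zeros(self.n_pictures, bool)
                                        if self.degenerate is None else self.degenerate))
        sidecar = {
            "layer": self.layer,
            "normalized": self.normalized,
            "meta": self.meta.to_dict(orient="list"),
            "attrs": {k: v for k, v in self.attrs.items()
                      if isinstance(v, (str, int, float, bool, list))},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "ActivationMatrix":
        path = Path(path)
        arr = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(values=arr["values"], meta=pd.DataFrame(sidecar["meta"]),
                   layer=sidecar["layer"], normalized=sidecar["normalized"],
                   degenerate=arr["degenerate"], attrs=sidecar.get("attrs", {}))


@dataclass
class CategoryProfileMatrix:
    """Categories x units matrix of mean normalized activations."""

    values: np.ndarray
    categories: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile values must be 2-D (categories x units)")
        if len(self.categories) != self.values.shape[0]:
            raise ValueError("category ids do not match the number of profile rows")

    @property
    def n_categories(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def row(self, category) -> np.ndarray:
        return self.values[list(self.categories).index(category)]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=pd.Index(self.categories, name="category"),
                     columns=[f"u{i}" for i in range((self.n_units))]).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CategoryProfileMatrix":
        df = pd.read_csv(path, index_col="category")
        return cls(values=df.to_numpy(float), categories=list(df.index))


def extract(backbone: Backbone, images: Sequence[np.ndarray], layer: str = "classifier",
            meta: pd.DataFrame | None = None) -> ActivationMatrix:
    """Run images through one named layer of a backbone.

    Returns a raw (un-normalized) :class:`ActivationMatrix` with one row per
    image and the layer's flattened width as columns.
    """
    available = backbone.layers
    if layer not in available:
        raise KeyError(f"unknown layer {layer!r}; backbone exposes {sorted(available)}")
    values = np.asarray(backbone.respond(images, layer), dtype=float)
    if values.ndim != 2 or values.shape[0] != len(images):
        raise ValueError("backbone returned a malformed response table")
    if values.shape[1] != available[layer]:
        raise ValueError(
            f"layer {layer!r} declared width {available[layer]} but returned {values.shape[1]}")
    if meta is None:
        meta = pd.DataFrame({"picture_id": np.arange(len(images)), "group": 0})
    return ActivationMatrix(values=values, meta=meta, layer=layer, normalized=False)


def normalize_unit_range(acts: ActivationMatrix | np.ndarray) -> ActivationMatrix:
    """Normalize each picture's responses to [0, 1] across units.

    Per row: (x - min) / (max - min).  Rows with zero range cannot be
    normalized; they become all-zero and are flagged ``degenerate`` rather
    than dropped.  The transform is idempotent.
    """
    if isinstance(acts, np.ndarray):
        acts = ActivationMatrix(values=acts,
                                meta=pd.DataFrame({"picture_id": np.arange(len(acts)),
                                                   "group": 0}))
    if acts.values.size == 0:
        raise ValueError("cannot normalize an empty activation table")
    vals = acts.values
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate = (span == 0).ravel()
    safe = np.where(span == 0, 1.0, span)
    out = (vals - lo) / safe
    out[degenerate] = 0.0
    return ActivationMatrix(values=out, meta=acts.meta.copy(), layer=acts.layer,
                            normalized=True, degenerate=degenerate, attrs=dict(acts.attrs))


def category_profile_matrix(acts: ActivationMatrix, labels: Sequence) -> CategoryProfileMatrix:
    """Average rows within category label to form the reference profiles."""
    labels = np.asarray(labels)
    if labels.shape[0] != acts.n_pictures:
        raise ValueError(
            f"{labels.shape[0]} labels for {acts.n_pictures} pictures")
    cats = sorted(pd.unique(labels).tolist())
    profiles = np.vstack([acts.values[labels == c].mean(axis=0) for c in cats])
    return CategoryProfileMatrix(values=profiles, categories=cats)
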
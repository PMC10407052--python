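"""Embedding coefficients: how well a scene's objects fit the learned categories.

The embedding coefficient of an object is the maximum Pearson correlation
between its normalized classifier-layer activation vector and any category's
mean activation profile; the matching category is the "embedded" category
(which need not agree with the dataset label). A picture's coefficient is
the unweighted mean over its bounding boxes, and the category-based variant
replaces each box's coefficient with the mean coefficient of its dataset
label before averaging. Pictures ranked by coefficient split into superior
and inferior embedded subsets per numerosity group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activations import (ActivationMatrix, Backbone, CategoryProfileMatrix,
                          extract, normalize_unit_range)

__all__ = [
    "EmbeddingError", "match_profile", "score_rows", "box_embedding",
    "picture_embedding", "category_based_embedding", "split_subsets",
]


class EmbeddingError(ValueError):
    """Degenerate input (e.g. a zero-variance activation vector)."""


def match_profile(vector: np.ndarray, profiles: CategoryProfileMatrix,
                  context: str = "") -> tuple:
    """Best-matching category and its Pearson coefficient for one vector."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size != profiles.n_units:
        raise ValueError(f"vector width {v.size} does not match profiles "
                         f"({profiles.n_units} units)")
    if np.std(v) < 1e-12:
        raise EmbeddingError(
            f"undefined correlation: zero-variance activation vector{' for ' + context if context else ''}")
    P = profiles.values
    p_std = P.std(axis=1)
    if np.any(p_std < 1e-12):
        raise EmbeddingError("a category profile row has zero variance")
    vc = v - v.mean()
    Pc = P - P.mean(axis=1, keepdims=True)
    r = (Pc @ vc) / (np.linalg.norm(Pc, axis=1) * np.linalg.norm(vc))
    best = int(np.argmax(r))
    return profiles.categories[best], float(r[best])


def score_rows(acts: ActivationMatrix, profiles: CategoryProfileMatrix) -> pd.DataFrame:
    """Embedding score of every row of an activation table.

    Used both for cropped-box activations and for the synthetic route where
    a whole picture's activation vector is scored directly. Returns a frame
    with best_category and coefficient per row, aligned with ``acts.meta``.
    """
    rows = []
    for k in range(acts.n_pictures):
        pid = acts.meta.iloc[k].get("picture_id", k)
        cat, r = match_profile(acts.values[k], profiles, context=f"picture {pid}")
        rows.append({"picture_id": pid, "best_category": cat, "coefficient": r})
    df = pd.DataFrame(rows)
    if "group" in acts.meta.columns:
        df["group"] = acts.meta["group"].to_numpy()
    return df


def box_embedding(backbone: Backbone, image: np.ndarray, box,
                  profiles: CategoryProfileMatrix) -> tuple:
    """Crop one bounding box, extract, normalize, and match against profiles.

    The crop is the rectangular box content (not the inscribed ellipse),
    resized by the backbone to its input contract.
    """
    crop = box.crop(np.asarray(image))
    acts = normalize_unit_range(extract(backbone, [crop], layer="classifier"))
    if acts.degenerate is not None and acts.degenerate[0]:
        raise EmbeddingError(f"undefined correlation: degenerate crop for box {box}")
    return match_profile(acts.values[0], profiles, context=f"box {box}")


def picture_embedding(backbone: Backbone, image: np.ndarray, boxes,
                      profiles: CategoryProfileMatrix) -> dict:
    """Mean embedding coefficient over a picture's boxes, details retained."""
    if not boxes:
        raise ValueError("picture has no bounding boxes to score")
    details = []
    for box in boxes:
        cat, r = box_embedding(backbone, image, box, profiles)
        details.append({"box": box, "best_category": cat, "coefficient": r})
    score = float(np.mean([d["coefficient"] for d in details]))
    return {"score": score, "boxes": details}


def category_based_embedding(box_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-picture scores after replacing box coefficients with label means.

    ``box_scores`` needs columns picture_id, label, coefficient (one row per
    box over the whole picture population). Label means are computed over
    all boxes globally, each box's coefficient is replaced by its label's
    mean, and pictures average their replaced values.
    """
    required = {"picture_id", "label", "coefficient"}
    missing = required - set(box_scores.columns)
    if missing:
        raise ValueError(f"box table lacks column(s) {sorted(missing)}")
    if box_scores["label"].isna().any():
        bad = box_scores.index[box_scores["label"].isna()].tolist()
        raise ValueError(f"unlabeled box(es) at rows {bad}")
    label_mean = box_scores.groupby("label")["coefficient"].mean()
    replaced = box_scores["label"].map(label_mean)
    per_picture = (box_scores.assign(category_coefficient=replaced)
                   .groupby("picture_id")["category_coefficient"].mean()
                   .rename("score").reset_index())
    return per_picture


@dataclass
class SubsetSplit:
    superior: pd.DataFrame
    inferior: pd.DataFrame

    def tag(self, picture_id) -> str:
        if picture_id in set(self.superior["picture_id"]):
            return "superior"
        if picture_id in set(self.inferior["picture_id"]):
            return "inferior"
        return "none"


def split_subsets(scores: pd.DataFrame, k: int = 50) -> SubsetSplit:
    """Top-k and bottom-k pictures by score within each numerosity group.

    Ties are broken deterministically by picture id. Every group must
    contain at least 2k pictures so the subsets cannot overlap.
    """
    required = {"picture_id", "group", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table lacks column(s) {sorted(missing)}")
    sup_parts, inf_parts = [], []
    for g, block in scores.groupby("group"):
        if len(block) < 2 * k:
            raise ValueError(f"group {g} has {len(block)} pictures; need >= {2 * k} "
                             f"for a top-{k}/bottom-{k} split")
        ordered = block.sort_values(["score", "picture_id"],
                                    ascending=[True, True], kind="mergesort")
        inf_parts.append(ordered.iloc[:k])
        sup_parts.append(ordered.iloc[-k:])
    return SubsetSplit(superior=pd.concat(sup_parts, ignore_index=True),
                       inferior=pd.concat(inf_parts, ignore_index=True))
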
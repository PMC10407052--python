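"""Synthetic inputs for every downstream stage.

Nothing here depends on external downloads: activation tables come from a
generative model with planted monotone units, category profiles are drawn
with a dominant diagonal, toy object images are procedural hue/texture
families, the mock backbone is a small trainable network satisfying the
Backbone contract, and human trial logs follow a supplied psychometric curve.

The activation model
--------------------
A picture in numerosity group ``g`` (1-based) with category ``c`` and
embedding fidelity ``phi`` is generated as::

    x = phi * signal + (1 - phi) * noise

where ``signal`` equals the category profile row on background units and a
deterministic ramp ``baseline_mean + slope_mean * (g - 1)`` on planted
increasing units (mirrored for decreasing units), and ``noise`` is i.i.d.
zero-truncated Gaussian with scale ``baseline_sigma * sigma_scale**(g - 1)``.
Consequences, all used by tests as ground truth:

* planted-unit population means ramp monotonically with the group;
* cross-picture noise shrinks geometrically with the group (sigma_scale);
* the Pearson correlation between a picture and its category profile grows
  monotonically with ``phi``, and so does its decodability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import color as skcolor
from skimage.transform import resize

from ._utils import rng_from, spawn_seeds, trunc_normal, trunc_normal_moments
from .activations import ActivationMatrix, CategoryProfileMatrix
from .config import ConfigError, SynthActivationConfig

__all__ = [
    "gen_category_profiles", "gen_activation_dataset", "population_moments",
    "gen_image_dataset", "MockBackbone", "train_mock_backbone",
    "untrained_backbone", "backbone_accuracy", "gen_trial_log",
]


# ---------------------------------------------------------------------------
# category profiles
# ---------------------------------------------------------------------------

def gen_category_profiles(n_categories: int, n_units: int, diag_strength: float = 0.5,
                          seed=0, baseline_mean: float = 0.2,
                          baseline_sigma: float = 0.1) -> CategoryProfileMatrix:
    """Draw category mean-activation profiles with a dominant preferred unit.

    Row ``i`` peaks at unit ``i`` (the category's own classifier unit) and
    carries baseline co-activation everywhere else; ``diag_strength`` in
    (0, 1] sets how far the peak rises above the rest of the row toward 1.
    """
    if n_categories > n_units:
        raise ConfigError(
            f"'n_categories' ({n_categories}) must not exceed 'n_units' ({n_units})")
    rng = rng_from(seed)
    if diag_strength >= 1.0:
        vals = np.zeros((n_categories, n_units))
        vals[np.arange(n_categories), np.arange(n_categories)] = 1.0
        return CategoryProfileMatrix(values=vals, categories=list(range(n_categories)))
    vals = trunc_normal(rng, baseline_mean, baseline_sigma, (n_categories, n_units))
    vals = np.clip(vals, 0.0, 1.0)
    rows = np.arange(n_categories)
    row_max = vals.max(axis=1)
    vals[rows, rows] = row_max + diag_strength * (1.0 - row_max)
    return CategoryProfileMatrix(values=vals, categories=list(range(n_categories)))


# ---------------------------------------------------------------------------
# planted-structure activation datasets
# ---------------------------------------------------------------------------

def _per_picture_fidelity(cfg: SynthActivationConfig, rng) -> np.ndarray:
    n = cfg.n_groups * cfg.n_pictures_per_group
    if cfg.embed_fidelity_spread == 0:
        return np.full(n, cfg.embed_fidelity)
    half = cfg.embed_fidelity_spread / 2.0
    phi = rng.uniform(cfg.embed_fidelity - half, cfg.embed_fidelity + half, n)
    return np.clip(phi, 0.0, 1.0)


def gen_activation_dataset(cfg: SynthActivationConfig,
                           profiles: CategoryProfileMatrix | None = None,
                           planted_units: tuple | None = None) -> ActivationMatrix:
    """Generate a raw (pre-normalization) activation table with planted structure.

    Metadata columns: ``picture_id``, ``group`` (1..n_groups), ``category``,
    ``fidelity``.  ``attrs`` records the planted increasing/decreasing unit
    indices, the profile matrix, and the generating configuration.  Identical
    config and seed give bit-identical output.  Pass the ``profiles`` and
    ``planted_units`` of a previously generated dataset to draw a second
    sample (e.g. a validation set) from the same underlying population.
    """
    seeds = spawn_seeds(cfg.seed, 4)
    if profiles is None:
        profiles = gen_category_profiles(cfg.n_categories, cfg.n_units,
                                         cfg.diag_strength, seed=seeds[0],
                                         baseline_mean=cfg.baseline_mean,
                                         baseline_sigma=cfg.baseline_sigma)
    elif profiles.n_units != cfg.n_units:
        raise ConfigError("'profiles' width does not match 'n_units'")

    rng_struct = rng_from(seeds[1])
    rng_pic = rng_from(seeds[2])
    rng_noise = rng_from(seeds[3])

    if planted_units is None:
        n_planted = cfg.n_increasing + cfg.n_decreasing
        planted = rng_struct.choice(cfg.n_units, size=n_planted, replace=False)
        inc_units = np.sort(planted[:cfg.n_increasing])
        dec_units = np.sort(planted[cfg.n_increasing:])
    else:
        inc_units = np.asarray(planted_units[0], dtype=int)
        dec_units = np.asarray(planted_units[1], dtype=int)
        if inc_units.size != cfg.n_increasing or dec_units.size != cfg.n_decreasing:
            raise ConfigError("'planted_units' sizes disagree with the configured counts")

    n_total = cfg.n_groups * cfg.n_pictures_per_group
    groups = np.repeat(np.arange(1, cfg.n_groups + 1), cfg.n_pictures_per_group)
    categories = rng_pic.integers(0, profiles.n_categories, n_total)
    phi = _per_picture_fidelity(cfg, rng_pic)

    signal = profiles.values[categories].copy()
    ramp_up = cfg.baseline_mean + cfg.slope_mean * (groups - 1)
    ramp_dn = cfg.baseline_mean + cfg.slope_mean * (cfg.n_groups - groups)
    signal[:, inc_units] = ramp_up[:, None]
    signal[:, dec_units] = ramp_dn[:, None]

    sigma_g = cfg.baseline_sigma * cfg.sigma_scale ** (groups - 1)
    noise = trunc_normal(rng_noise, cfg.baseline_mean,
                         np.broadcast_to(sigma_g[:, None], (n_total, cfg.n_units)),
                         (n_total, cfg.n_units))

    values = phi[:, None] * signal + (1.0 - phi[:, None]) * noise
    meta = pd.DataFrame({
        "picture_id": [f"g{g}_p{i}" for g, i in
                       zip(groups, np.tile(np.arange(cfg.n_pictures_per_group), cfg.n_groups))],
        "group": groups,
        "category": categories,
        "fidelity": phi,
    })
    return ActivationMatrix(
        values=values, meta=meta, layer="classifier", normalized=False,
        attrs={
            "increasing_units": inc_units.tolist(),
            "decreasing_units": dec_units.tolist(),
            "profiles": profiles,
            "config": asdict(cfg),
        })


def population_moments(cfg: SynthActivationConfig) -> pd.DataFrame:
    """Exact population mean/std of planted units per group.

    Computed from the closed-form moments of the zero-truncated Gaussian at
    the configured scalar fidelity; exact when ``embed_fidelity_spread`` is 0.
    Serves as the independent oracle for the effect-size contract.
    """
    g = np.arange(1, cfg.n_groups + 1)
    sigma_g = cfg.baseline_sigma * cfg.sigma_scale ** (g - 1)
    m_noise, s_noise = trunc_normal_moments(np.full_like(sigma_g, cfg.baseline_mean), sigma_g)
    phi = cfg.embed_fidelity
    ramp_up = cfg.baseline_mean + cfg.slope_mean * (g - 1)
    ramp_dn = cfg.baseline_mean + cfg.slope_mean * (cfg.n_groups - g)
    return pd.DataFrame({
        "group": g,
        "inc_mean": phi * ramp_up + (1 - phi) * m_noise,
        "inc_std": (1 - phi) * s_noise,
        "dec_mean": phi * ramp_dn + (1 - phi) * m_noise,
        "dec_std": (1 - phi) * s_noise,
        "noise_mean": m_noise,
        "noise_std": s_noise,
    })


# ---------------------------------------------------------------------------
# toy labeled images and the mock backbone
# ---------------------------------------------------------------------------

def gen_image_dataset(n_categories: int, n_per_category: int, image_size: int = 64,
                      seed=0) -> tuple[list[np.ndarray], np.ndarray]:
    """Procedural labeled object images: one hue/texture family per category.

    Each image is a smooth random luminance texture rendered in the
    category's hue band on a black-free full frame (backgrounds are added
    later when objects are composed into scenes). Deterministic per seed.
    """
    if image_size < 32:
        raise ConfigError(f"'image_size' must be >= 32, got {image_size}")
    if n_categories < 1 or n_per_category < 1:
        raise ConfigError("'n_categories' and 'n_per_category' must be positive")
    rng = rng_from(seed)
    images, labels = [], []
    for c in range(n_categories):
        base_hue = c / n_categories
        for _ in range(n_per_category):
            coarse = rng.uniform(0.25, 1.0, (6, 6))
            value = resize(coarse, (image_size, image_size), order=3, mode="reflect",
                           anti_aliasing=False)
            hue = (base_hue + rng.uniform(-0.02, 0.02)) % 1.0
            sat = np.clip(0.85 + 0.1 * rng.standard_normal(), 0.6, 1.0)
            hsv = np.stack([np.full_like(value, hue), np.full_like(value, sat),
                            np.clip(value, 0, 1)], axis=-1)
            rgb = (skcolor.hsv2rgb(hsv) * 255).astype(np.uint8)
            images.append(rgb)
            labels.append(c)
    return images, np.asarray(labels)


def _as_rgb_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    return np.clip(img, 0.0, 1.0)


@dataclass
class MockBackbone:
    """A small two-layer network satisfying the Backbone layer contract.

    ``classifier`` exposes the category read-out (one unit per trained
    category); ``last_conv`` exposes the hidden feature layer, playing the
    role of the pre-classifier stage. Inputs of any size are resized to
    ``input_size`` squared RGB; responses are deterministic.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    input_size: int = 32
    trained: bool = False
    identifier: str = "mock"
    classes: np.ndarray | None = None

    @property
    def layers(self) -> dict[str, int]:
        return {"classifier": self.W2.shape[1], "last_conv": self.W1.shape[1]}

    def preprocess(self, images: Sequence[np.ndarray]) -> np.ndarray:
        rows = []
        for img in images:
            img = _as_rgb_float(img)
            if img.shape[:2] != (self.input_size, self.input_size):
                img = resize(img, (self.input_size, self.input_size),
                             anti_aliasing=True, mode="reflect")
            rows.append(img.ravel())
        return np.asarray(rows)

    def respond(self, images: Sequence[np.ndarray], layer: str) -> np.ndarray:
        X = self.preprocess(images)
        hidden = np.maximum(X @ self.W1 + self.b1, 0.0)
        if layer == "last_conv":
            return hidden
        if layer == "classifier":
            return hidden @ self.W2 + self.b2
        raise KeyError(f"unknown layer {layer!r}; available: {sorted(self.layers)}")

    def predict(self, images: Sequence[np.ndarray]) -> np.ndarray:
        logits = self.respond(images, "classifier")
        idx = logits.argmax(axis=1)
        return idx if self.classes is None else self.classes[idx]


def _augmented_renders(image: np.ndarray, rng, input_size: int, n_augment: int,
                       scale_range: tuple[float, float]) -> list[np.ndarray]:
    """Plain resize plus renders at random scale/position on black canvas."""
    out = [resize(_as_rgb_float(image), (input_size, input_size),
                  anti_aliasing=True, mode="reflect")]
    for _ in range(n_augment):
        s = rng.uniform(*scale_range)
        side = max(4, int(round(s * input_size)))
        small = resize(_as_rgb_float(image), (side, side), anti_aliasing=True, mode="reflect")
        canvas = np.zeros((input_size, input_size, 3))
        y = rng.integers(0, input_size - side + 1)
        x = rng.integers(0, input_size - side + 1)
        canvas[y:y + side, x:x + side] = small
        out.append(canvas)
    return out


def train_mock_backbone(images: Sequence[np.ndarray], labels: Sequence, *,
                        epochs: int = 60, seed=0, hidden: int = 128,
                        input_size: int = 32, n_augment: int = 3,
                        scale_range: tuple[float, float] = (0.3, 1.0)) -> MockBackbone:
    """Train the mock backbone for object classification on toy images.

    Training images are augmented with random-scale, random-position renders
    on a black canvas so the classifier units also respond to small objects
    inside composed scenes (the scene route downsamples whole scenes to the
    backbone input size). Seeded and reproducible.
    """
    from sklearn.neural_network import MLPClassifier

    labels = np.asarray(labels)
    if len(labels) != len(images):
        raise ValueError(f"{len(labels)} labels for {len(images)} images")
    if np.unique(labels).size < 2:
        raise ValueError("degenerate label set: need at least 2 categories")

    seeds = spawn_seeds(int(seed), 2)
    rng = rng_from(seeds[0])
    X, y = [], []
    for img, lab in zip(images, labels):
        for render in _augmented_renders(img, rng, input_size, n_augment, scale_range):
            X.append(render.ravel())
            y.append(lab)
    X = np.asarray(X)
    y = np.asarray(y)

    clf = MLPClassifier(hidden_layer_sizes=(hidden,), activation="relu", solver="adam",
                        learning_rate_init=1e-3, max_iter=epochs,
                        random_state=seeds[1] % (2**31), early_stopping=False)
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return MockBackbone(W1=clf.coefs_[0], b1=clf.intercepts_[0],
                        W2=clf.coefs_[1], b2=clf.intercepts_[1],
                        input_size=input_size, trained=True,
                        identifier="mock-trained", classes=clf.classes_)


def untrained_backbone(n_categories: int, *, input_size: int = 32, hidden: int = 128,
                       seed=0) -> MockBackbone:
    """Same architecture, random weights: the untrained-network control."""
    rng = rng_from(seed)
    d = input_size * input_size * 3
    W1 = rng.standard_normal((d, hidden)) / np.sqrt(d)
    W2 = rng.standard_normal((hidden, n_categories)) / np.sqrt(hidden)
    return MockBackbone(W1=W1, b1=np.zeros(hidden), W2=W2, b2=np.zeros(n_categories),
                        input_size=input_size, trained=False,
                        identifier="mock-untrained", classes=np.arange(n_categories))


def backbone_accuracy(backbone: MockBackbone, images, labels) -> float:
    return float(np.mean(backbone.predict(images) == np.asarray(labels)))


# ---------------------------------------------------------------------------
# synthetic human trial logs
# ---------------------------------------------------------------------------

def _curve_rate(curve, d: int) -> float:
    """Accept a PsychCurve, a mapping distance -> rate, or a callable."""
    if callable(curve):
        return float(curve(d))
    if hasattr(curve, "rate_at"):
        return float(curve.rate_at(d))
    return float(curve[d])


def gen_trial_log(curves: dict, n_participants: int = 12, trials_per_cell: int = 50,
                  seed=0, numbers: Sequence[int] = range(1, 8),
                  lapse: float = 0.0, bias: float = 0.0,
                  pool_size: int = 50) -> pd.DataFrame:
    """Simulate button-press logs of the two-picture numerosity comparison.

    ``curves`` maps a condition tag (e.g. ``superior`` / ``inferior``) to a
    psychometric curve giving P(report "A has more") at signed distance
    ``n_A - n_B``. Side assignment of A is counterbalanced within each cell;
    one row per trial with columns participant, trial, n_left, n_right,
    picture ids, condition, response, rt, and the per-participant lapse/bias
    actually applied. With 7 numbers, 2 conditions and 50 trials per cell a
    participant contributes 7 * 7 * 50 * 2 = 4900 rows.
    """
    numbers = list(numbers)
    for cond, curve in curves.items():
        for a in numbers:
            for b in numbers:
                p = _curve_rate(curve, a - b)
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"curve for condition {cond!r} gives rate {p} at distance {a - b}; "
                        "rates must lie in [0, 1]")
    rows = []
    seeds = spawn_seeds(int(seed), n_participants)
    for p_idx in range(n_participants):
        rng = rng_from(seeds[p_idx])
        trial = 0
        for cond, curve in curves.items():
            for a in numbers:
                for b in numbers:
                    # exact counterbalance of which side carries stimulus A
                    a_left = np.zeros(trials_per_cell, dtype=bool)
                    a_left[:trials_per_cell // 2 + (trials_per_cell % 2)] = True
                    rng.shuffle(a_left)
                    p_report = (1 - lapse) * _curve_rate(curve, a - b) + lapse * 0.5
                    for t in range(trials_per_cell):
                        report_a = rng.random() < p_report
                        p_left = float(report_a if a_left[t] else not report_a)
                        p_left = np.clip(p_left + bias, 0.0, 1.0)
                        resp = "left" if rng.random() < p_left else "right"
                        n_left, n_right = (a, b) if a_left[t] else (b, a)
                        rows.append({
                            "participant": p_idx,
                            "trial": trial,
                            "n_left": n_left,
                            "n_right": n_right,
                            "pic_left": f"{cond}_g{n_left}_p{rng.integers(pool_size)}",
                            "pic_right": f"{cond}_g{n_right}_p{rng.integers(pool_size)}",
                            "condition": cond,
                            "response": resp,
                            "rt": float(np.round(rng.lognormal(-0.5, 0.3), 4)),
                            "lapse": lapse,
                            "bias": bias,
                        })
                        trial += 1
    return pd.DataFrame(rows)
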
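"""Configuration objects for every pipeline stage.

Each dataclass validates itself on construction and raises
:class:`ConfigError` naming the offending field, so misconfiguration fails
early rather than deep inside a simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


class ConfigError(ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


def _positive(name, value):
    if not value > 0:
        raise ConfigError(f"'{name}' must be > 0, got {value!r}")


def _nonneg(name, value):
    if value < 0:
        raise ConfigError(f"'{name}' must be >= 0, got {value!r}")


def _in_range(name, value, lo, hi, lo_open=False, hi_open=False):
    ok = (value > lo if lo_open else value >= lo) and (value < hi if hi_open else value <= hi)
    if not ok:
        raise ConfigError(f"'{name}' must lie in {'(' if lo_open else '['}{lo}, {hi}"
                          f"{')' if hi_open else ']'}, got {value!r}")


@dataclass
class SynthActivationConfig:
    """Generative model of classifier-layer responses with planted structure.

    The generator plants two kinds of structure on top of a truncated-Gaussian
    background: a set of units whose population mean ramps monotonically with
    the numerosity group (``n_increasing`` up, ``n_decreasing`` down, step
    ``slope_mean`` per group), and a per-group shrinkage of cross-picture
    noise (``sigma_scale`` multiplies the noise scale once per group), which
    together emulate the rising-mean / falling-variability signature of group
    coding. ``embed_fidelity`` mixes each picture's vector between its
    category's mean profile (plus the planted ramp) and pure noise, so one
    knob controls how well a picture correlates with its category profile and
    how cleanly its numerosity can be read out.
    """

    n_units: int = 1000
    n_groups: int = 7
    n_pictures_per_group: int = 150
    n_increasing: int = 48
    n_decreasing: int = 13
    slope_mean: float = 0.05
    sigma_scale: float = 0.9
    baseline_mean: float = 0.2
    baseline_sigma: float = 0.1
    embed_fidelity: float = 0.6
    embed_fidelity_spread: float = 0.0  # per-picture fidelity ~ U(f - s/2, f + s/2), clipped to [0, 1]
    n_categories: int = 20
    diag_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_units", "n_groups", "n_pictures_per_group", "n_categories"):
            _positive(name, getattr(self, name))
        for name in ("n_increasing", "n_decreasing"):
            _nonneg(name, getattr(self, name))
        if self.n_increasing + self.n_decreasing > self.n_units:
            raise ConfigError("'n_increasing' + 'n_decreasing' exceeds 'n_units'")
        if self.n_categories > self.n_units:
            raise ConfigError("'n_categories' must not exceed 'n_units'")
        _in_range("sigma_scale", self.sigma_scale, 0, 1, lo_open=True)
        _in_range("embed_fidelity", self.embed_fidelity, 0, 1)
        _nonneg("embed_fidelity_spread", self.embed_fidelity_spread)
        _nonneg("slope_mean", self.slope_mean)
        _positive("baseline_sigma", self.baseline_sigma)
        _nonneg("baseline_mean", self.baseline_mean)
        _in_range("diag_strength", self.diag_strength, 0, 1, lo_open=True)


@dataclass
class SceneLayoutConfig:
    """Geometry of composed ellipse scenes.

    Defaults are a 1/8 linear scale-down of the full-size layout (2000 px
    canvas, 4x4 grid of 500 px cells, total object area 250*250*7 px^2) with
    every length scaled identically so the geometry is unchanged; areas scale
    by the square of the linear factor.
    """

    canvas_size: int = 250
    grid_rows: int = 4
    grid_cols: int = 4
    target_total_area: float = 31.25 * 31.25 * 7  # (250/8)^2 * 7
    scale_jitter: float = 0.25
    n_candidates: int = 1000
    fade_kernel: int = 15
    max_retries: int = 100
    seed: int = 0

    @property
    def cell_size(self) -> float:
        return self.canvas_size / self.grid_rows

    def __post_init__(self):
        _positive("canvas_size", self.canvas_size)
        _positive("grid_rows", self.grid_rows)
        _positive("grid_cols", self.grid_cols)
        if self.canvas_size % self.grid_rows or self.canvas_size % self.grid_cols:
            raise ConfigError("'canvas_size' must be divisible by the grid so cells tile the canvas")
        _positive("target_total_area", self.target_total_area)
        _in_range("scale_jitter", self.scale_jitter, 0, 1, hi_open=True)
        _positive("n_candidates", self.n_candidates)
        if self.fade_kernel % 2 == 0 or self.fade_kernel < 1:
            raise ConfigError(f"'fade_kernel' must be an odd positive size, got {self.fade_kernel}")
        _positive("max_retries", self.max_retries)


@dataclass
class DecoderConfig:
    """Training configuration for the numerosity read-out network."""

    hidden: int = 2000
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 200
    early_stopping: bool = True
    validation_fraction: float = 0.1
    n_iter_no_change: int = 10
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        _positive("hidden", self.hidden)
        _positive("learning_rate", self.learning_rate)
        _positive("max_epochs", self.max_epochs)
        _positive("batch_size", self.batch_size)
        _in_range("validation_fraction", self.validation_fraction, 0, 1, lo_open=True, hi_open=True)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (synthetic-activation route)."""

    seed: int = 0
    outdir: str = "numsense_run"
    synth_train: SynthActivationConfig = field(default_factory=lambda: SynthActivationConfig(
        n_units=300, n_pictures_per_group=500, n_increasing=30, n_decreasing=9))
    synth_val: SynthActivationConfig = field(default_factory=lambda: SynthActivationConfig(
        n_units=300, n_pictures_per_group=150, n_increasing=30, n_decreasing=9,
        embed_fidelity=0.25, embed_fidelity_spread=0.4, baseline_sigma=0.2))
    decoder: DecoderConfig = field(default_factory=lambda: DecoderConfig(hidden=500))
    selection_alpha: float = 0.1
    trials_per_cell: int = 100
    trials_per_cell_embedding: int = 33
    comparison_reps: int = 10
    subset_k: int = 50
    resample_n_pick: int = 500
    resample_reps: int = 10
    rsa_min_references: int = 12
    resume: bool = True

    def __post_init__(self):
        _in_range("selection_alpha", self.selection_alpha, 0, 1, lo_open=True)
        _positive("trials_per_cell", self.trials_per_cell)
        _positive("trials_per_cell_embedding", self.trials_per_cell_embedding)
        _positive("comparison_reps", self.comparison_reps)
        _positive("subset_k", self.subset_k)
        _positive("rsa_min_references", self.rsa_min_references)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("synth_train", SynthActivationConfig),
                         ("synth_val", SynthActivationConfig),
                         ("decoder", DecoderConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)
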
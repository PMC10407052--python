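# numsense

Numerosity perception — the rapid, non-counting sense of *how many* objects a
scene contains — can be read out of an object-classification network without
any number-specific training. When scenes with 1–7 objects are passed through
a classifier network and each picture's category-layer responses are
normalized to [0, 1] across units, two signatures of **group coding** emerge:
the upper decile of per-unit mean activations rises with the number of
objects, and the lower decile of the per-unit standard deviations falls —
co-activation "sidebands" of non-preferred category units accumulate and
stabilize as scenes get fuller. `numsense` implements that analysis as a
tested, reusable pipeline for researchers in computational cognitive
neuroscience and psychophysics:

- **Stimulus synthesis** — mosaic compositions, area-matched ellipse scenes
  (soft Gaussian-faded elliptical patches on a 4×4 virtual grid with
  non-overlap jitter and total-area matching), white-noise overlays,
  foreground/background clip variants, and Fourier phase scrambling.
- **Activation analysis** — per-picture unit-range normalization, per-group
  unit statistics, decile summaries with a 500×10 resampling protocol, ANOVA
  trend tests.
- **Decoding** — screening for units whose mean activation is strictly
  monotone over the 7 groups with p < 0.1 on every consecutive-pair Welch
  test, then a small read-out network (selected units → 2000 hidden units →
  1 output; the output *is* the numerosity estimate).
- **Comparison task** — simulated two-picture "which has more?" trials,
  7×7 performance matrices, psychometric curves over signed numerical
  distance −6…6, human trial-log ingestion, and noise-robustness sweeps.
- **Embedding coefficients** — the maximum Pearson correlation between an
  object's normalized activation vector and any category's mean profile;
  superior/inferior embedded subset splits and their behavioral contrast.
- **RSA** — condition-level and picture-wise representational similarity
  matrices, compared across agents with one-sided Wilcoxon signed-rank tests
  and FDR control.
- **Synthetic generators** — every stage runs without downloads: a planted
  generative model of category-layer activations (monotone units, per-group
  variance shrinkage, an embedding-fidelity knob), procedural labeled
  images, a small trainable backbone exposing `classifier` and `last_conv`
  layers, and psychometric trial-log simulation.

## Worked example

```python
import numpy as np
from scipy import stats
from numsense import (gen_activation_dataset, normalize_unit_range,
                      select_monotone_units, train_decoder, decode,
                      run_comparison, psychometric)
from numsense.config import SynthActivationConfig, DecoderConfig

train = gen_activation_dataset(SynthActivationConfig(
    n_units=300, n_pictures_per_group=500, n_increasing=30, n_decreasing=9, seed=5))
train_n = normalize_unit_range(train)
units = select_monotone_units(train_n, alpha=0.1)
model = train_decoder(train_n, units, cfg=DecoderConfig(hidden=500, seed=6))
```

Running `python examples/02_decoding_psychometrics.py` (which continues this
script onto a noisier held-out set) prints:

```
selected 30 increasing and 9 decreasing units (of 30+9 planted)
held-out Spearman(decoded, true n) = 0.756
decoded group means (true 1..7): [3.   3.27 3.54 4.   4.35 4.9  5.42]

  d    S(d) = P(report A > B)
  -3   0.110 ####
  +0   0.505 ####################
  +3   0.890 ####################################
```

The screening recovers exactly the planted monotone units; decoded means
increase with the true count but are compressed toward the middle
(overestimation at 1, underestimation at 7 — the bias a squared-error
read-out shares with human estimation); and collapsing the 7×7 comparison
matrix onto numerical distance yields the S-shaped curve of the numerical
distance effect, crossing 50% at distance 0.

The other scripts in `examples/` walk through the group-coding statistics,
the embedding-subset contrast (superior ≈ 99% vs inferior ≈ 83% correct at
|d| ≥ 3), the image route with a trained toy backbone and noise sweeps, and
human-log ingestion plus RSA.

An end-to-end orchestrated run (data → statistics → selection → decoder →
comparison → embedding → RSA, with artifacts and provenance on disk) is

```bash
numsense run --seed 7 --outdir my_run     # or: numsense stimgen --variant ellipse
```

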
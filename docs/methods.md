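# Methods

This note documents the models, procedures, and numerical choices behind
`numsense`, in the order a run encounters them.

## The generative model of category-layer activations

The synthetic route replaces a real backbone with an explicit generative
model whose structure mirrors what the analysis is designed to detect. A
picture in numerosity group *g* (1-based, default 7 groups) with category
*c* and embedding fidelity φ is

```
x = φ · signal + (1 − φ) · noise
```

- `signal` equals the category's mean activation profile on background
  units, and a deterministic ramp on planted units:
  `baseline_mean + slope_mean · (g − 1)` for increasing units, mirrored for
  decreasing units.
- `noise` is i.i.d. Gaussian truncated at zero (activations are
  non-negative, matching the post-rectification character of layer
  responses), with scale `baseline_sigma · sigma_scale^(g−1)` — the
  per-group geometric shrinkage that produces the falling-variability
  signature.

Three consequences are used as ground truth throughout the tests: planted
population means ramp monotonically in *g* (closed-form moments via the
truncated-normal distribution are exposed by `population_moments` and
checked against samples at 4 standard errors); cross-picture noise shrinks
geometrically; and both the Pearson correlation between a picture and its
category profile and the cleanliness of its numerosity read-out increase
monotonically in φ — one knob ties the embedding coefficient to
discriminability, which is exactly the effect the embedding analysis
measures downstream.

Defaults mirror the full-scale study conditions where they exist (7 groups,
150 validation pictures per group, 48 increasing / 13 decreasing planted
units in a 1000-unit layer) and are otherwise desk-scale choices:
`baseline_mean 0.2`, `baseline_sigma 0.1`, `slope_mean 0.05`,
`sigma_scale 0.9`. The pipeline's validation set uses
`embed_fidelity 0.25 ± 0.2` with `baseline_sigma 0.2`, chosen so the
psychometric curves sit in the non-saturated range reported for real
validation scenes (~66–90% correct at distances 1–3) rather than at
ceiling. `embed_fidelity_spread` draws per-picture fidelities uniformly
around the mean; the closed-form moments are exact only at zero spread.

One caveat worth knowing: per-picture range normalization divides every
unit by that picture's max−min, which injects a small shared noise term
into all normalized values. At desk scale this can mask the
standard-deviation decile ordering in the *synthetic* tables (it does not
at full layer widths, and does not affect the raw tables, on which the
decile contract is tested); the mean-decile ordering survives either way.

## Stimulus construction

Composed scenes follow the published geometry at 1/8 linear scale (240 px
canvas, 4×4 virtual grid, total object area 30·30·7 px²; all lengths scale
together so the geometry is unchanged). Objects are clipped to the ellipse
inscribed in their bounding box; the rim is softened by convolving the
binary ellipse mask with a normalized `fade_kernel × fade_kernel` Gaussian
(default 15, σ = kernel/6) and masking to the interior, so outside pixels
stay exactly black. Per-item scale factors are drawn within ±25% of the
mean size and the best of 1000 seeded candidate combinations (minimum
absolute deviation of summed area from the target) is kept. Items are
anchored to distinct grid cells with jittered centers and strictly disjoint
non-black supports; when an item is larger than its cell — which the
published area numbers imply for 1–2 items — the layout (cells and jitter)
is re-drawn up to `max_retries` times rather than forcing containment.
"White noise" is i.i.d. uniform 8-bit per channel; noise overlays are
additive and clipped. Phase scrambling adds a random Hermitian-symmetric
phase field (the phase of the FFT of a real noise image, DC forced to zero
so the mean survives) to every channel, preserving the amplitude spectrum
to numerical precision before the final rounding into [0, 255].

Two scene families serve different purposes. Area-matched ellipse scenes
hold total object area constant across numerosities and are used wherever
low-level magnitude cues must be controlled (group statistics, the
untrained-network control). Mosaic pictures and `natural` scenes keep item
size independent of count, as in ordinary photographs, and are used for the
image-route decoding analyses: at desk scale, area matching shrinks items
as 1/n below the toy backbone's effective resolution at n ≥ 5, which
destroys the count signal for reasons of pixel budget, not of principle.

## The mock backbone

A deliberately small two-layer network (input image resized to 48×48 RGB →
128 rectified hidden units → one output unit per category) stands in for a
full classification backbone; only the layer-response contract matters
(`classifier` and `last_conv` accessors, deterministic evaluation).
Training images are procedural hue/texture families, augmented with renders
at random scale and position on a black canvas so classifier units also
respond to small objects inside composed scenes. The untrained control is
the same architecture with Gaussian weights scaled by fan-in.

## Unit selection and the read-out network

A unit is *increasing* when its group means rise strictly across all seven
groups **and** every consecutive-pair two-sample test has p < α (default
0.1, two-sided; no multiple-testing correction — the α is a screening
threshold). Welch's unequal-variance test is used because picture pools
are different pictures in different groups and admit no pairing unit. The
read-out is a single-hidden-layer regressor (default 2000 units) with one
linear output trained by squared error with adam at learning rate 1e-3 for
at most 100 epochs, early-stopped on a seeded 10% validation split. Squared
error produces the compressive estimation bias (overestimating 1,
underestimating 7) without any extra mechanism.

A scale note: the monotone screen passes only a few percent of units at
full layer width (61 of 1000). A desk-scale backbone has a 10–20-unit
classifier layer, so the expected number of survivors is below one at any
feasible sample size — confirmed empirically across scene families and
sample sizes up to 1000 scenes per group. Image-route analyses therefore
read out from the full classifier layer (`UnitSet.full`), which subsumes
any screened subset; the screening operation itself is validated on the
synthetic route, where planted effect sizes make recovery exact.

## The comparison task

Each trial draws one picture from the sample group and one from the test
group (with replacement across trials, without replacement within a trial)
and reports "A > B" iff the decoded value of A exceeds that of B; exact
ties fall to a seeded fair coin. Off-diagonal cell pairs (a, b)/(b, a)
share their draws and tie-coins in mirrored form, so S(d) + S(−d) = 1 holds
*exactly* within a single run for d ≠ 0, while diagonal trials stay
independent so S(0) is a genuine binomial sample around one half.
Psychometric rates are trial-weighted means over the cells at each signed
distance; percent correct is max(S, 1−S). Human logs are ingested with the
convention that cell (a, b) pools trials with a on the left, reporting the
fraction answered "left"; side counterbalancing makes this equivalent to
the sample/test reading for any curve with S(d) + S(−d) = 1. A
configurable side-bias screen (left-response rate outside [0.35, 0.65] by
default) flags rather than excludes.

## Embedding coefficients

An object's embedding coefficient is the maximum Pearson correlation
between its normalized classifier vector and any category's mean profile;
the crop is the rectangular box content. Picture scores are unweighted
means over boxes; the category-based variant replaces each box's
coefficient with its dataset-label's global mean before averaging.
Superior/inferior subsets are the top/bottom k (default 50) per numerosity
group, with deterministic tie-breaking by picture id.

## RSA

Condition-level RSMs fold the superior and inferior S-curves into two 7×7
discriminability blocks, cell (i, j) = mean of |S(i−j)−0.5| and
|S(j−i)−0.5| with a zero diagonal; the cross-condition cells carry the two
conditions' mean discriminability at that distance (constant cross-blocks
would inject identical structure into every agent's RSM and bias the
permutation null). The exact filling of curves into an RSM is an
interpretive choice; the alternative construction — concatenating the two
13-point curves and taking absolute rate differences — is available via
`method="concat"`. Picture-wise RSMs use 1 − Pearson between win-rate
profiles with the two pictures' own entries excluded. Candidates are
scored by Spearman correlation of upper triangles against ≥ 12 reference
RSMs, tested one-sided by Wilcoxon signed-rank with joint
Benjamini–Hochberg control.

A statistical caveat, discovered and verified by simulation while building
the null tests: when references share almost all their structure (as they
must for a matching candidate to correlate ≥ 0.95), the per-reference
correlations of a *permuted* candidate are strongly dependent — the
signed-rank test then has roughly one effective observation and will call
the permuted agent "significant" whenever its single alignment draw is
positive. The informative control comparison is therefore the pairwise
FDR-controlled test between the matching and shuffled candidates, which
separates them essentially always; the shuffled agent's mean correlation is
centered on zero by construction. Similarly, a decoder *retrained* on
shuffled labels inherits the random per-group means of its labels (7
effective clusters), so its held-out rank correlation is individually noisy
though zero-mean across shuffles; the clean picture-level null is the
condition-shuffled evaluation, where decoded estimates are paired with a
permuted group assignment.

## Problem sizes and defaults

Unit tests run on small instances (≈100–300 units, 60–500 pictures per
group); the acceptance-level analyses use 500 units with 1000 pictures per
group for selection/decoding, 150 per group for validation and embedding
splits (k=50, 33 trials per cell, 10 repetitions, as in the behavioral
design), 400 mosaics per group for the image route, and 100-trial cells
with 10 repetitions for psychometrics. These sizes were chosen so every
planted effect is measured with comfortable margins while a full run stays
around a minute on one CPU. What passing tests show is that the pipeline
detects and quantifies the structures it targets when they are present and
stays silent when they are absent; synthetic generators cannot certify
behavior on real photographs, where object segmentation, clutter and
category structure are far richer than any planted model.
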
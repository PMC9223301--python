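# Methods

## The measures

`colorfuzen` quantifies the irregularity of a color image
`U(i, j, k)` (height `H`, width `W`, channels `K = 3`) with three
bidimensional fuzzy entropy measures.  All three follow the same
scheme: slide a template over the image, grade the similarity of every
pair of templates with a continuous fuzzy membership, and report the
negative log of the conditional probability that templates similar at
embedding size `m` remain similar at size `m + 1`.

For two templates with Chebyshev (maximum absolute component) distance
`d`, the similarity is

    D = exp(-d^n / r),

with fuzzy power `n` (default 2, a Gaussian kernel) and tolerance `r`
(default 0.15).  For each template size, `Φ^m` is the mean of `D` over
all ordered pairs of distinct template anchors, and the entropy is
`ln(Φ^m / Φ^{m+1})`.  Crucially, the anchor set is *identical* at both
sizes — `N_m = (W - m)(H - m)` anchors per plane (times `K - m` depth
positions for the cube variant) — and the self-pair is excluded for
all three measures (the standard fuzzy-entropy convention; the
templates being compared are always distinct).

The three template geometries:

* **FuzEnC2D** — `m x m` square windows in each channel separately;
  the result is a vector of `K` per-channel entropies.  Useful when
  individual channels (hue, luminance, ...) carry distinct meaning.
* **FuzEnV2D** — `m x m x m` cubes spanning channels, anchor depth
  `c = 1 .. K - m`.  The `(m+1)`-cube must fit in `K` channels, so
  `1 <= m <= K - 1` (`m` in {1, 2} for trichromatic images).
* **FuzEnM2D** — `m x m x K` cuboids always spanning the full channel
  depth, with a single depth anchor.  `m` is unconstrained by `K`.

Because the `m`-template is geometrically nested inside the
`(m+1)`-template, `d_{m+1} >= d_m` holds for every pair, hence
`Φ^{m+1} <= Φ^m` and the entropy is non-negative; a constant image
yields exactly 0.  `Φ` can never reach 0 with the Gaussian membership
(every pair contributes `D > 0`), so the log-ratio is always defined —
this is asserted, not branched on.

### Parameters

| parameter | meaning | default | notes |
| --- | --- | --- | --- |
| `m` | template side (pixels) | 2 | the experiments' operating point |
| `n` | fuzzy power | 2.0 | any positive real; 2 = Gaussian kernel |
| `r` | tolerance | 0.15 | in units of channel SD (images are standardized first) |

`r` is applied directly, *not* rescaled by a standard deviation:
the preprocessing contract standardizes every channel to unit SD, which
makes the "absolute r" and "r x SD" conventions of the 1-D
fuzzy-entropy literature coincide.  If you skip normalization, `r` is
in raw intensity units.

## Preprocessing

Images are read as RGB floats in [0, 1], optionally converted to HSV
(hexcone; hue scaled to [0, 1]) or YUV (BT.601), then normalized.
Conversion happens before normalization, since the transformed spaces
are the analysis substrate.  Normalization is per-channel by default —
HSV/YUV channels live on incommensurate scales, and a single global
scale would let one channel dominate the Chebyshev distance — with a
`global` mode one switch away.  A zero-variance channel is passed
through mean-subtracted with a warning so constant fixtures produce
entropy 0 rather than NaN.  Hue is treated as a linear coordinate; its
circularity is *not* wrapped into the distance (a known limitation:
textures straddling the red hue wrap-around will look more irregular in
H than they are).

Region-of-interest selection is a pure centered crop (odd remainders
drop the bottom/right row/column).  No lesion segmentation is
performed; on dermoscopy images the user should crop inside the lesion.

## Numerical implementation

Templates are flattened so the `m`-template components come first; one
numba pass per anchor-pair block yields both distances.  Distances are
buffered per row block (~4M pairs) and the memberships for a whole
vector of tolerances are evaluated with vectorized `exp` over the
buffer, so an `r`-sweep costs barely more than a single evaluation.
Accumulation is plain float64; agreement with the brute-force
transcription is ~1e-15 on test sizes (tested gate: 1e-10).  The
brute-force oracle (`colorfuzen.oracle`) is a literal nested-loop
transcription sharing no code with the kernels and refuses inputs with
more than 500 anchors.

Cost is quadratic in the anchor count: a 128x128 channel at `m = 2`
has ~16k anchors and ~1.3e8 unordered pairs (a few seconds per
channel); the validation experiments below use 64x64–320x320 images,
which keeps each full experiment in the minutes range on one core.

## Synthetic validation data

**MIX2D(p) / MIX3D(p)** interpolate between a deterministic sinusoidal
grid (`X(i,j) = sin(2*pi*i/T) + sin(2*pi*j/T)`, period `T = 12`; the
3-D variant adds `sin(2*pi*k/T)`) and i.i.d. uniform noise on
`[-sqrt(3), sqrt(3)]` (zero mean, unit variance) via an i.i.d.
Bernoulli(p) mask: `MIX = (1 - Z) X + Z Y`.  Noise is drawn for every
pixel and then masked, so the `p = 0` image is exactly seed-independent
and the mask statistics are testable in isolation.  Mean entropy must
increase strictly with `p`; this is the core calibration experiment
(10 seeded 64x64 images per `p`, `m` in {1, 2}, `r = 0.15`).

**Composite fixture.**  A seeded stationary colored texture standing in
for photographic texture sets: a shared luminance-like base (an
oriented quasi-periodic grating whose phase drifts with a smooth random
field, plus correlated noise at two spatial scales) perturbed per
channel by a weaker independent field.  Two design choices matter and
were made on fidelity grounds: (i) the grating is *not* exactly
periodic — photographic textures never are, and exact repeats create
degenerate zero-distance template pairs; (ii) channels share one
structural base (correlation ~0.9), as in colorized texture
photographs.  With independent channels the inter-channel measures
operate in a regime dominated by a few nearest pairs and acquire a
strong finite-size bias.

What the synthetic data does **not** emulate: illumination gradients,
JPEG artifacts, specular highlights, hair/ruler occlusions of real
dermoscopy, or the heavy-tailed intensity statistics of natural images.
Passing the validation suite shows the measures behave as designed on
controlled irregularity and stationary texture; it does not by itself
establish clinical discriminative power.

## Co-occurrence baseline

Per-channel min–max quantization into `Ng = 8` levels (constant
channels map to bin 1).  2-D matrices: 4 orientations (0/45/90/135 deg;
0 deg = rightward along rows, counterclockwise in image coordinates) x
4 distances (1, 2, 4, 8).  3-D matrices: the 13 non-antiparallel
directions of the 26-neighborhood x the same distances; displacements
whose depth component exceeds `K - 1` have no valid pairs and are
excluded from the average rather than zero-filled (zero-filling would
bias every feature toward its degenerate value; 18 of 52 matrices are
empty at `K = 3`).  Matrices are symmetric by default, which makes the
row/column marginals equal and fixes the otherwise ambiguous mean in
the variance feature.  Feature entropy uses the natural log (base-2
flag available), with `0 log 0 := 0`; correlation is defined as 0 when
a marginal SD vanishes.  Averaged features are insensitive to the
orientation sign convention.

## Statistics layer

Mann–Whitney U (two-sided; exact null distribution for untied samples
of <= 20 per group, tie-corrected normal approximation otherwise),
Cohen's d with (n-1)-weighted pooled SD, and ROC metrics: AUC by the
Mann–Whitney pair-counting identity (ties count 1/2), operating point
at maximal Youden's J with ties broken toward higher specificity.
Score polarity defaults to auto (chosen so AUC >= 0.5) and is reported;
fix it with `direction=` for strict reproducibility across feature
sets.  The Youden rule is a convention — equally defensible choices
(accuracy maximization, fixed specificity) move the operating point
but not the AUC.  No multiple-testing correction is applied.

## Known limitations and observed behavior

* **r-monotonicity is not a law.**  Entropy usually decreases as the
  tolerance `r` grows, and does so for FuzEnC2D and FuzEnV2D at every
  tested grid point.  For FuzEnM2D with large templates (`m >= 3`,
  i.e. cuboids of >= 27 voxels) the entropy-vs-r curve can pass through
  a minimum inside [0.06, 0.48] and rise again.  This reproduces on
  real photographs, not just on generated fixtures, and follows from
  the derivative of `ln(Φ^m/Φ^{m+1})` in `r`: its sign compares the
  softmin-weighted mean of `d_m^2` with that of `d_{m+1}^2` under
  *different* weightings, which is not sign-definite.  The sweep
  experiment reports such violations rather than hiding them.
* Entropy estimates from templates much larger than the texture's
  correlation length sit in a few-dominant-pair regime with large
  finite-size bias; compare sub-image and full-image values before
  trusting absolute numbers.
* Only `K = 3` channels are exercised; the code paths accept other
  depths for FuzEnM2D but they are untested territory.
* Hue circularity, as noted above.
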
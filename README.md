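# colorfuzen

Colored bidimensional fuzzy entropy for texture irregularity analysis.

Texture irregularity is a workhorse feature in biomedical image
analysis — dermoscopy of pigmented skin lesions in particular, where
malignant melanoma tends to show more irregular color texture than
benign melanocytic nevi.  Entropy-based texture measures are well
established for gray-scale images; `colorfuzen` implements the fuzzy
entropy family for *color* images, in both a single-channel and two
multi-channel (inter-channel) forms, together with everything needed to
validate and apply them: synthetic irregularity processes, color-space
preprocessing, a gray-level co-occurrence (Haralick) baseline, and a
two-group statistics layer (Mann–Whitney U, Cohen's d, ROC/AUC).

## The measures

For an image `U(i, j, k)` with `H x W` pixels and `K = 3` channels,
templates of embedding size `m` are compared with the Chebyshev
distance `d` (maximum absolute component difference) and graded by a
continuous fuzzy membership

    D = exp(-d^n / r)        (n = 2: Gaussian kernel; r: tolerance).

With `Φ^m` the mean similarity over all ordered pairs of distinct
template anchors (the anchor grid is the same at sizes `m` and `m+1`,
`N_m = (W-m)(H-m)` per plane), each measure is the log-ratio

    FuzEn = ln(Φ^m / Φ^{m+1}) >= 0.

* **FuzEnC2D** — `m x m` windows per channel; returns `[FuzEnC_K1,
  FuzEnC_K2, FuzEnC_K3]`.
* **FuzEnV2D** — `m x m x m` cubes across channels (`1 <= m <= K-1`).
* **FuzEnM2D** — `m x m x K` full-depth cuboids (any `m >= 1`).

Higher values mean more irregular texture.  A constant image scores
exactly 0; i.i.d. noise scores highest.  See `docs/methods.md` for the
full model description, conventions and limitations.

## Worked example

Two synthetic MIX2D(p) images — `p` is the probability that a pixel of
a periodic sinusoidal grid is replaced by uniform noise — analyzed at
the standard operating point (`m = 2`, `n = 2`, `r = 0.15`) after
per-channel standardization:

```python
import numpy as np
from colorfuzen import (MixProcessSpec, generate_mix2d_multichannel,
                        normalize_channels, EntropyParams, fuzenc2d,
                        fuzenv2d, fuzenm2d)

params = EntropyParams(m=2, n=2, r=0.15)
for p in (0.1, 0.9):
    spec = MixProcessSpec(p=p, height=64, width=64)
    img = normalize_channels(generate_mix2d_multichannel(spec, (1, 2, 3)))
    print(f"MIX2D(p={p}):")
    print("  FuzEnC2D =", np.round(fuzenc2d(img, params).values, 3))
    print("  FuzEnV2D =", round(fuzenv2d(img, params).scalar, 3))
    print("  FuzEnM2D =", round(fuzenm2d(img, params).scalar, 3))
```

prints

```
MIX2D(p=0.1):
  FuzEnC2D = [1.53  1.531 1.558]
  FuzEnV2D = 3.482
  FuzEnM2D = 2.871
MIX2D(p=0.9):
  FuzEnC2D = [5.028 5.064 5.046]
  FuzEnV2D = 12.784
  FuzEnM2D = 9.465
```

The nearly-periodic image (`p = 0.1`) scores low on every measure; the
nearly-random one (`p = 0.9`) scores 3–4x higher, per channel and
across channels.

## Command line

```
colorfuzen generate --kind mix2d-rgb --p 0.5 --count 10 --out-dir imgs/
colorfuzen entropy imgs/*.tiff --method v2d --m 2 --r 0.15 --out ent.csv
colorfuzen haralick imgs/*.tiff --mode 3d
colorfuzen compare groupA.csv groupB.csv --out stats.csv
colorfuzen run experiment.yaml
```

`colorfuzen run` executes a YAML experiment manifest end to end
(parameter sensitivity sweep, MIX irregularity curve, sub-image
consistency, or a two-group feature study); outputs are CSV files whose
headers record the package version, a manifest hash and all parameters,
and re-running a manifest reproduces them bit-identically.

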
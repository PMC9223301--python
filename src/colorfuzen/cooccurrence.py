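"""Gray-level co-occurrence matrices (2-D and 3-D) and Haralick features.

The comparison baseline for the entropy measures: each channel (or the
quantized volume) is reduced to Ng gray levels, co-occurrence matrices
are accumulated for a set of orientations and inter-pixel distances,
the six commonly used Haralick features are computed per matrix, and
the features are averaged over all non-empty matrices.

Conventions (fixed and documented, since averaged features are
insensitive to them):

* Orientation 0 deg is displacement (0, +d) (along rows, rightward);
  45/90/135 deg follow counterclockwise in image coordinates.
* Matrices are symmetric by default (pair counted in both orders),
  which makes the row/column marginals equal and dissolves the
  ambiguity in the variance feature's mean.
* Quantization is per-channel min-max into Ng equal-width bins.
* Feature entropy uses the natural logarithm by default (base-2
  available), with the convention 0 * log 0 = 0.
* 3-D displacements whose depth component exceeds the channel count
  produce empty matrices; these are excluded from averaging (zero
  filling would bias features toward degenerate values).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ColorImage

__all__ = [
    "GLCMConfig", "GLCM", "HaralickFeatures",
    "quantize", "glcm_2d", "glcm_3d", "haralick", "averaged_haralick",
    "ORIENTATIONS_2D", "ORIENTATIONS_3D",
]

# 0, 45, 90, 135 degrees as (row, col) unit displacements
ORIENTATIONS_2D: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1))

# the 13 unique non-antiparallel directions of the 26-neighborhood,
# as (row, col, depth) displacements
ORIENTATIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)
assert len(ORIENTATIONS_3D) == 13


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization and displacement grid for co-occurrence analysis."""

    n_levels: int = 8
    distances: tuple[int, ...] = (1, 2, 4, 8)
    symmetric: bool = True
    log_base: str = "e"  # "e" or "2" for the entropy feature

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be positive")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


@dataclass(frozen=True)
class GLCM:
    """One normalized co-occurrence matrix P(i, j), levels 1..Ng."""

    P: np.ndarray
    orientation: tuple
    distance: int
    valid_pairs: int

    @property
    def empty(self) -> bool:
        return self.valid_pairs == 0


@dataclass(frozen=True)
class HaralickFeatures:
    energy: float
    contrast: float
    correlation: float
    variance: float
    homogeneity: float
    entropy: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.energy, self.contrast, self.correlation,
                self.variance, self.homogeneity, self.entropy)

    FIELDS = ("energy", "contrast", "correlation",
              "variance", "homogeneity", "entropy")


def quantize(channel: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniform min-max binning into integer levels 1..Ng.

    The maximum maps to bin Ng; a constant channel maps entirely to
    bin 1 (the documented degenerate path).
    """
    ch = np.asarray(channel, dtype=np.float64)
    lo, hi = ch.min(), ch.max()
    if hi == lo:
        return np.ones(ch.shape, dtype=np.int64)
    bins = np.floor((ch - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.minimum(bins, n_levels)


def _accumulate(src: np.ndarray, dst: np.ndarray, n_levels: int,
                symmetric: bool) -> tuple[np.ndarray, int]:
    pairs = src.size
    counts = np.bincount((src.ravel() - 1) * n_levels + (dst.ravel() - 1),
                         minlength=n_levels * n_levels
                         ).reshape(n_levels, n_levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    P = counts / total if total > 0 else counts
    return P, pairs


def glcm_2d(plane: np.ndarray, orientation: tuple[int, int], distance: int,
            n_levels: int = 8, symmetric: bool = True) -> GLCM:
    """Co-occurrence matrix of a quantized plane at one displacement."""
    q = np.asarray(plane)
    if q.ndim != 2:
        raise ValueError("glcm_2d expects a 2-D quantized plane")
    di, dj = orientation[0] * distance, orientation[1] * distance
    h, w = q.shape
    if abs(di) >= h or abs(dj) >= w:
        return GLCM(np.zeros((n_levels, n_levels)), orientation, distance, 0)
    r0, r1 = max(0, -di), min(h, h - di)
    c0, c1 = max(0, -dj), min(w, w - dj)
    src = q[r0:r1, c0:c1]
    dst = q[r0 + di:r1 + di, c0 + dj:c1 + dj]
    P, pairs = _accumulate(src, dst, n_levels, symmetric)
    return GLCM(P, orientation, distance, pairs)


def glcm_3d(volume: np.ndarray, orientation: tuple[int, int, int],
            distance: int, n_levels: int = 8, symmetric: bool = True) -> GLCM:
    """Co-occurrence matrix of a quantized volume at one 3-D displacement.

    Displacements whose depth component times the distance exceeds
    K - 1 have no in-bounds pair and yield an empty (flagged) matrix.
    """
    q = np.asarray(volume)
    if q.ndim != 3:
        raise ValueError("glcm_3d expects a 3-D quantized volume")
    off = tuple(o * distance for o in orientation)
    if any(abs(o) >= s for o, s in zip(off, q.shape)):
        return GLCM(np.zeros((n_levels, n_levels)), orientation, distance, 0)
    slices_src, slices_dst = [], []
    for o, s in zip(off, q.shape):
        a0, a1 = max(0, -o), min(s, s - o)
        slices_src.append(slice(a0, a1))
        slices_dst.append(slice(a0 + o, a1 + o))
    src = q[tuple(slices_src)]
    dst = q[tuple(slices_dst)]
    P, pairs = _accumulate(src, dst, n_levels, symmetric)
    return GLCM(P, orientation, distance, pairs)


def haralick(glcm: GLCM, log_base: str = "e") -> HaralickFeatures:
    """The six Haralick features of one non-empty GLCM.

    energy      = sum P^2
    contrast    = sum_n n^2 * sum_{|i-j|=n} P(i,j)
    correlation = (sum ij P(i,j) - mu_x mu_y) / (sigma_x sigma_y),
                  defined as 0 when sigma_x sigma_y = 0 (constant image)
    variance    = sum (i - mu_x)^2 P(i,j)
    homogeneity = sum P(i,j) / (1 + (i-j)^2)
    entropy     = -sum P log P   (0 log 0 := 0)

    Levels are indexed 1..Ng.  With symmetric matrices mu_x = mu_y, so
    the variance feature's mean is unambiguous.
    """
    if glcm.empty:
        raise ValueError("empty GLCM: no valid pixel pairs")
    P = glcm.P
    ng = P.shape[0]
    lev = np.arange(1, ng + 1, dtype=np.float64)
    ii = lev[:, None]
    jj = lev[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((lev * px).sum())
    mu_y = float((lev * py).sum())
    sig_x = float(np.sqrt(((lev - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((lev - mu_y) ** 2 * py).sum()))

    energy = float((P ** 2).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    if sig_x * sig_y > 0:
        correlation = float(((ii * jj * P).sum() - mu_x * mu_y)
                            / (sig_x * sig_y))
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * P).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    if log_base == "2":
        entropy /= np.log(2.0)
    return HaralickFeatures(energy, contrast, correlation,
                            variance, homogeneity, entropy)


def _average(features: list[HaralickFeatures]) -> HaralickFeatures:
    arr = np.array([f.as_tuple() for f in features])
    return HaralickFeatures(*arr.mean(axis=0))


def averaged_haralick(img: ColorImage, config: GLCMConfig = GLCMConfig(),
                      mode: str = "per_channel_2d"):
    """Haralick features averaged over all (orientation, distance) matrices.

    ``mode="per_channel_2d"`` returns a list with one HaralickFeatures
    per channel (4 orientations x len(distances) matrices each);
    ``mode="volume_3d"`` returns a single HaralickFeatures from the 13
    orientations x len(distances) volumetric matrices (empty matrices
    excluded from the average).
    """
    if mode == "per_channel_2d":
        out = []
        for k in range(img.n_channels):
            q = quantize(img.channel(k), config.n_levels)
            feats = []
            for orient in ORIENTATIONS_2D:
                for d in config.distances:
                    g = glcm_2d(q, orient, d, config.n_levels,
                                config.symmetric)
                    if not g.empty:
                        feats.append(haralick(g, config.log_base))
            if not feats:
                raise ValueError(f"channel {img.labels[k]}: all GLCMs empty")
            out.append(_average(feats))
        return out
    if mode == "volume_3d":
        q = np.stack([quantize(img.channel(k), config.n_levels)
                      for k in range(img.n_channels)], axis=-1)
        feats = []
        for orient in ORIENTATIONS_3D:
            for d in config.distances:
                g = glcm_3d(q, orient, d, config.n_levels, config.symmetric)
                if not g.empty:
                    feats.append(haralick(g, config.log_base))
        if not feats:
            raise ValueError("all 3-D GLCMs empty")
        return _average(feats)
    raise ValueError(f"unknown mode {mode!r}")
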
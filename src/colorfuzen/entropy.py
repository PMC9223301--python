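"""Colored bidimensional fuzzy entropy: FuzEnC2D, FuzEnV2D, FuzEnM2D.

All three measures estimate the irregularity of an image as the
negative natural logarithm of the conditional probability that
templates similar at embedding size m remain similar at size m+1,
where similarity between two templates is graded by the continuous
fuzzy membership exp(-d^n / r) of their Chebyshev (max-abs) distance d.

They differ only in the template geometry:

* FuzEnC2D -- m x m square windows in each channel independently;
  returns one entropy per channel.
* FuzEnV2D -- m x m x m cubes spanning channels; the anchor depth runs
  over 1..K-m, so m is limited to K-1 (m in {1, 2} for K = 3).
* FuzEnM2D -- m x m x K cuboids always spanning the full channel
  depth; m is unconstrained by K.

For every measure the anchor set is identical at sizes m and m+1
(N_m = (W-m)(H-m) per plane, times K-m depth positions for V2D), and
the self-pair is excluded.  Phi^m is the grand mean similarity over
ordered anchor pairs; the entropy is ln(Phi^m / Phi^{m+1}).  Since the
m-template is nested in the (m+1)-template, d_{m+1} >= d_m for every
pair, hence Phi^{m+1} <= Phi^m and the entropy is always >= 0; a
constant image gives exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._kernel import pair_similarity_sums
from .image import ColorImage

__all__ = [
    "EntropyParams", "PhiEstimate", "EntropyResult",
    "phi_pair_2d", "fuzenc2d", "fuzenv2d", "fuzenm2d", "compute_entropy",
]


class DegenerateInputError(ValueError):
    """Raised when fewer than two template anchors exist."""


@dataclass(frozen=True)
class EntropyParams:
    """(m, n, r): embedding size, fuzzy power, tolerance.

    Defaults m=2, n=2 (Gaussian membership), r=0.15 — the operating
    point used throughout the validation experiments.
    """

    m: int = 2
    n: float = 2.0
    r: float = 0.15

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding size m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.n <= 0:
            raise ValueError("fuzzy power n must be positive")


@dataclass(frozen=True)
class PhiEstimate:
    """The Phi^m / Phi^{m+1} pair behind one entropy value."""

    phi_m: float
    phi_m1: float
    n_patterns: int

    @property
    def entropy(self) -> float:
        return float(np.log(self.phi_m / self.phi_m1))


@dataclass(frozen=True)
class EntropyResult:
    """Outcome of one entropy computation.

    ``values`` holds K entries for C2D (channel order) and a single
    entry for V2D/M2D; ``phis`` retains the underlying Phi estimates
    for diagnostics.
    """

    method: str
    params: EntropyParams
    values: tuple[float, ...]
    labels: tuple[str, ...]
    phis: tuple[PhiEstimate, ...] = field(default=(), repr=False)

    @property
    def scalar(self) -> float:
        if len(self.values) != 1:
            raise ValueError(f"{self.method} result is not scalar")
        return self.values[0]


# ---------------------------------------------------------------------------
# template extraction

def _check_plane_size(h: int, w: int, m: int) -> None:
    if h < m + 1 or w < m + 1:
        raise ValueError(
            f"image {h}x{w} too small for embedding size m={m} "
            f"(needs at least {m + 1} pixels per axis)")


def _templates_c2d(plane: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    h, w = plane.shape
    _check_plane_size(h, w, m)
    win = sliding_window_view(plane, (m + 1, m + 1))  # (H-m, W-m, m+1, m+1)
    order = ([(s, t) for s in range(m) for t in range(m)]
             + [(s, t) for s in range(m + 1) for t in range(m + 1)
                if s == m or t == m])
    cols = [win[:, :, s, t].reshape(-1) for s, t in order]
    return np.ascontiguousarray(np.stack(cols, axis=1)), m * m


def _templates_v2d(vol: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    h, w, k = vol.shape
    if m > k - 1:
        raise ValueError(
            f"FuzEnV2D requires 1 <= m <= K-1 (= {k - 1}); got m={m}")
    _check_plane_size(h, w, m)
    win = sliding_window_view(vol, (m + 1, m + 1, m + 1))
    # shape (H-m, W-m, K-m, m+1, m+1, m+1); anchors include depth
    order = ([(e, f, g) for e in range(m) for f in range(m) for g in range(m)]
             + [(e, f, g) for e in range(m + 1) for f in range(m + 1)
                for g in range(m + 1) if e == m or f == m or g == m])
    cols = [win[:, :, :, e, f, g].reshape(-1) for e, f, g in order]
    return np.ascontiguousarray(np.stack(cols, axis=1)), m ** 3


def _templates_m2d(vol: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    h, w, k = vol.shape
    _check_plane_size(h, w, m)
    win = sliding_window_view(vol, (m + 1, m + 1), axis=(0, 1))
    # shape (H-m, W-m, K, m+1, m+1); anchor depth fixed, full-K cuboid
    order = ([(g, e, f) for g in range(k) for e in range(m) for f in range(m)]
             + [(g, e, f) for g in range(k) for e in range(m + 1)
                for f in range(m + 1) if e == m or f == m])
    cols = [win[:, :, g, e, f].reshape(-1) for g, e, f in order]
    return np.ascontiguousarray(np.stack(cols, axis=1)), m * m * k


def _phi_from_templates(T: np.ndarray, csub: int, n: float,
                        rs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n_anchors = T.shape[0]
    if n_anchors < 2:
        raise DegenerateInputError("fewer than two template anchors")
    sum_m, sum_m1 = pair_similarity_sums(T, csub, float(n),
                                         np.asarray(rs, dtype=np.float64))
    denom = n_anchors * (n_anchors - 1) / 2.0  # unordered pairs
    return sum_m / denom, sum_m1 / denom, n_anchors


# ---------------------------------------------------------------------------
# public operations

def phi_pair_2d(plane: np.ndarray, params: EntropyParams) -> PhiEstimate:
    """Phi^m, Phi^{m+1} and the anchor count for a single channel."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("phi_pair_2d expects a 2-D plane")
    T, csub = _templates_c2d(plane, params.m)
    phi_m, phi_m1, n_anchors = _phi_from_templates(
        T, csub, params.n, np.array([params.r]))
    return PhiEstimate(float(phi_m[0]), float(phi_m1[0]), n_anchors)


def fuzenc2d(img: ColorImage, params: EntropyParams) -> EntropyResult:
    """Single-channel colored fuzzy entropy: one value per channel."""
    phis = []
    for k in range(img.n_channels):
        try:
            phis.append(phi_pair_2d(img.channel(k), params))
        except ValueError as exc:
            raise type(exc)(f"channel {img.labels[k]}: {exc}") from exc
    return EntropyResult("C2D", params, tuple(p.entropy for p in phis),
                         img.labels, tuple(phis))


def fuzenv2d(img: ColorImage, params: EntropyParams) -> EntropyResult:
    """Inter-channel fuzzy entropy over m x m x m cubes (m <= K-1)."""
    T, csub = _templates_v2d(img.pixels, params.m)
    phi_m, phi_m1, n_anchors = _phi_from_templates(
        T, csub, params.n, np.array([params.r]))
    phi = PhiEstimate(float(phi_m[0]), float(phi_m1[0]), n_anchors)
    return EntropyResult("V2D", params, (phi.entropy,), ("U",), (phi,))


def fuzenm2d(img: ColorImage, params: EntropyParams) -> EntropyResult:
    """Inter-channel fuzzy entropy over full-depth m x m x K cuboids."""
    T, csub = _templates_m2d(img.pixels, params.m)
    phi_m, phi_m1, n_anchors = _phi_from_templates(
        T, csub, params.n, np.array([params.r]))
    phi = PhiEstimate(float(phi_m[0]), float(phi_m1[0]), n_anchors)
    return EntropyResult("M2D", params, (phi.entropy,), ("U",), (phi,))


_METHODS = {"c2d": fuzenc2d, "v2d": fuzenv2d, "m2d": fuzenm2d}


def compute_entropy(img: ColorImage, method: str,
                    params: EntropyParams) -> EntropyResult:
    """Dispatch on method name in {"c2d", "v2d", "m2d"}."""
    try:
        fn = _METHODS[method.lower()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    return fn(img, params)


def entropy_r_sweep(img: ColorImage, method: str, m: int, n: float,
                    rs: np.ndarray) -> np.ndarray:
    """Entropies for a vector of tolerances r at fixed (method, m, n).

    The pairwise distance pass is shared across all r values, so a
    tolerance sweep costs barely more than a single evaluation.
    Returns an array of shape (len(rs),) for V2D/M2D and (K, len(rs))
    for C2D.
    """
    rs = np.asarray(rs, dtype=np.float64)
    method = method.lower()
    if method == "c2d":
        out = []
        for k in range(img.n_channels):
            T, csub = _templates_c2d(
                np.asarray(img.channel(k), dtype=np.float64), m)
            phi_m, phi_m1, _ = _phi_from_templates(T, csub, n, rs)
            out.append(np.log(phi_m / phi_m1))
        return np.stack(out)
    if method == "v2d":
        T, csub = _templates_v2d(img.pixels, m)
    elif method == "m2d":
        T, csub = _templates_m2d(img.pixels, m)
    else:
        raise ValueError(f"unknown method {method!r}")
    phi_m, phi_m1, _ = _phi_from_templates(T, csub, n, rs)
    return np.log(phi_m / phi_m1)
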
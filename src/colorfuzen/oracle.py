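"""Brute-force reference implementation of the three entropy measures.

A literal nested-loop transcription of the defining sums, sharing no
code with the optimized kernels: plain Python loops, ``math.exp``, no
vectorization.  It exists solely as the ground truth for equivalence
tests and refuses inputs with more than ``MAX_ANCHORS`` template
anchors to guard against accidental large runs.
"""

from __future__ import annotations

import math

import numpy as np

from .image import ColorImage
from .entropy import EntropyParams

__all__ = ["oracle_phi_plane", "oracle_entropy", "MAX_ANCHORS"]

MAX_ANCHORS = 500


def _mean_similarity_2d(plane, anchors, size, n, r):
    """Phi at one template size: mean over anchors of each anchor's mean
    similarity to all other anchors' windows (self excluded)."""
    phis = []
    for (i, j) in anchors:
        total = 0.0
        for (a, b) in anchors:
            if (a, b) == (i, j):
                continue
            d = 0.0
            for s in range(size):
                for t in range(size):
                    diff = abs(plane[i + s][j + t] - plane[a + s][b + t])
                    if diff > d:
                        d = diff
            total += math.exp(-(d ** n) / r)
        phis.append(total / (len(anchors) - 1))
    return sum(phis) / len(phis)


def oracle_phi_plane(plane, params: EntropyParams):
    """(phi_m, phi_m1, entropy) for one channel, by exhaustive loops."""
    plane = [list(map(float, row)) for row in np.asarray(plane)]
    h, w = len(plane), len(plane[0])
    m = params.m
    anchors = [(i, j) for i in range(h - m) for j in range(w - m)]
    if len(anchors) > MAX_ANCHORS:
        raise RuntimeError(f"oracle guard: {len(anchors)} anchors > {MAX_ANCHORS}")
    if len(anchors) < 2:
        raise ValueError("fewer than two anchors")
    phi_m = _mean_similarity_2d(plane, anchors, m, params.n, params.r)
    phi_m1 = _mean_similarity_2d(plane, anchors, m + 1, params.n, params.r)
    return phi_m, phi_m1, math.log(phi_m / phi_m1)


def _mean_similarity_3d(vol, anchors, se, sf, sg, n, r):
    """Phi over 3-D templates of extents (se, sf, sg) at the anchors."""
    phis = []
    for (i, j, k) in anchors:
        total = 0.0
        for (a, b, c) in anchors:
            if (a, b, c) == (i, j, k):
                continue
            d = 0.0
            for e in range(se):
                for f in range(sf):
                    for g in range(sg):
                        diff = abs(vol[i + e][j + f][k + g]
                                   - vol[a + e][b + f][c + g])
                        if diff > d:
                            d = diff
            total += math.exp(-(d ** n) / r)
        phis.append(total / (len(anchors) - 1))
    return sum(phis) / len(phis)


def _as_nested(img: ColorImage):
    return [[[float(v) for v in col] for col in row] for row in img.pixels]


def oracle_entropy(img: ColorImage, params: EntropyParams, method: str):
    """Entropy value(s) for one method by exhaustive enumeration.

    Returns a list of per-channel values for "c2d", a single float for
    "v2d"/"m2d".
    """
    method = method.lower()
    m = params.m
    if method == "c2d":
        return [oracle_phi_plane(img.channel(k), params)[2]
                for k in range(img.n_channels)]

    vol = _as_nested(img)
    h, w, kk = img.height, img.width, img.n_channels
    if method == "v2d":
        if m > kk - 1:
            raise ValueError("oracle: V2D requires m <= K-1")
        anchors = [(i, j, c) for i in range(h - m) for j in range(w - m)
                   for c in range(kk - m)]
        if len(anchors) > MAX_ANCHORS:
            raise RuntimeError("oracle guard exceeded")
        phi_m = _mean_similarity_3d(vol, anchors, m, m, m, params.n, params.r)
        phi_m1 = _mean_similarity_3d(vol, anchors, m + 1, m + 1, m + 1,
                                     params.n, params.r)
        return math.log(phi_m / phi_m1)
    if method == "m2d":
        anchors = [(i, j, 0) for i in range(h - m) for j in range(w - m)]
        if len(anchors) > MAX_ANCHORS:
            raise RuntimeError("oracle guard exceeded")
        phi_m = _mean_similarity_3d(vol, anchors, m, m, kk, params.n, params.r)
        phi_m1 = _mean_similarity_3d(vol, anchors, m + 1, m + 1, kk,
                                     params.n, params.r)
        return math.log(phi_m / phi_m1)
    raise ValueError(f"unknown method {method!r}")
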
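"""Synthetic validation textures: MIX processes and deterministic fixtures.

MIX2D(p) / MIX3D(p) are stochastic image families that interpolate
between a fully periodic pattern (p = 0) and pure noise (p = 1): every
pixel of a deterministic sinusoidal grid X is replaced, with
independent probability p, by a draw from a zero-mean unit-variance
uniform law.  Formally, with Z ~ Bernoulli(p) i.i.d. per pixel and
Y ~ Uniform(-sqrt(3), sqrt(3)) i.i.d. per pixel,

    MIX(p) = (1 - Z) * X + Z * Y,
    X(i, j)    = sin(2*pi*i/T) + sin(2*pi*j/T)          (2-D),
    X(i, j, k) = sin(2*pi*i/T) + sin(2*pi*j/T) + sin(2*pi*k/T)  (3-D),

with period T = 12 pixels by default.  An entropy measure worth its
salt must increase monotonically with p.

Noise is drawn for *every* pixel and then masked, so the p = 0 image is
exactly seed-independent and the Bernoulli mask statistics can be
tested in isolation.

Deterministic fixtures (constant, checkerboard, sinusoidal) and a
seeded stationary ``composite`` colored texture are also provided; the
composite stands in for non-redistributable photographic texture sets
in parameter-sensitivity and sub-image-consistency experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ColorImage

__all__ = [
    "MixProcessSpec", "FixtureSpec",
    "generate_mix2d", "generate_mix3d", "generate_mix2d_multichannel",
    "generate_fixture",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class MixProcessSpec:
    """Parameters of a MIX2D/MIX3D realization.

    p       -- irregularity probability in [0, 1]
    height, width -- image size in pixels (each >= period)
    depth   -- 1 for a MIX2D plane, 3 for a MIX3D volume
    period  -- period T of the deterministic sinusoidal component
    seed    -- RNG seed; identical spec + seed is bit-reproducible
    """

    p: float
    height: int = 256
    width: int = 256
    depth: int = 1
    period: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.depth not in (1, 3):
            raise ValueError("depth must be 1 (MIX2D) or 3 (MIX3D)")
        if self.period < 2:
            raise ValueError("period must be at least 2 pixels")
        if self.height < self.period or self.width < self.period:
            raise ValueError("image must span at least one period")


def _sinusoid_2d(height: int, width: int, period: int) -> np.ndarray:
    i = np.arange(height, dtype=np.float64)[:, None]
    j = np.arange(width, dtype=np.float64)[None, :]
    return np.sin(2 * np.pi * i / period) + np.sin(2 * np.pi * j / period)


def _mix(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    y = rng.uniform(-_SQRT3, _SQRT3, size=x.shape)
    z = rng.random(size=x.shape) < p
    return np.where(z, y, x)


def generate_mix2d(spec: MixProcessSpec) -> ColorImage:
    """One MIX2D(p) plane (ColorImage with a single channel)."""
    if spec.depth != 1:
        raise ValueError("generate_mix2d requires depth=1")
    x = _sinusoid_2d(spec.height, spec.width, spec.period)
    rng = np.random.default_rng(spec.seed)
    return ColorImage(_mix(x, spec.p, rng), space="generic", labels=("K1",))


def generate_mix3d(spec: MixProcessSpec) -> ColorImage:
    """A MIX3D(p) volume of three channels.

    The deterministic component is separable, so at p = 0 channel k is
    the 2-D sinusoid shifted by the constant sin(2*pi*k/T).
    """
    if spec.depth != 3:
        raise ValueError("generate_mix3d requires depth=3")
    base = _sinusoid_2d(spec.height, spec.width, spec.period)
    k = np.arange(3, dtype=np.float64)
    x = base[:, :, None] + np.sin(2 * np.pi * k / spec.period)[None, None, :]
    rng = np.random.default_rng(spec.seed)
    return ColorImage(_mix(x, spec.p, rng), space="generic")


def generate_mix2d_multichannel(spec: MixProcessSpec,
                                seeds: tuple[int, int, int]) -> ColorImage:
    """Stack three independent MIX2D(p) planes as channels K1..K3."""
    if len(seeds) != 3:
        raise ValueError("exactly three seeds required")
    planes = [
        generate_mix2d(MixProcessSpec(p=spec.p, height=spec.height,
                                      width=spec.width, depth=1,
                                      period=spec.period, seed=s)).channel(0)
        for s in seeds
    ]
    return ColorImage(np.stack(planes, axis=-1), space="generic")


@dataclass(frozen=True)
class FixtureSpec:
    """A deterministic (or seeded composite) texture fixture.

    kind       -- constant | checkerboard | sinusoidal | composite
    height, width, depth -- image dimensions
    value      -- pixel value of the constant fixture
    levels     -- the two alternating values of the checkerboard
    period     -- spatial period (checkerboard cell = period/2)
    amplitude  -- sinusoidal amplitude
    seed       -- composite kind only
    """

    kind: str
    height: int = 64
    width: int = 64
    depth: int = 3
    value: float = 0.5
    levels: tuple[float, float] = (0.0, 1.0)
    period: int = 8
    amplitude: float = 1.0
    seed: int = 0

    _KINDS = ("constant", "checkerboard", "sinusoidal", "composite")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.height < 2 or self.width < 2 or self.depth < 1:
            raise ValueError("fixture dimensions too small")


def _composite_texture(spec: FixtureSpec) -> np.ndarray:
    """Stationary seeded colored texture emulating a colorized
    photographic weave.

    One shared luminance-like base — an oriented quasi-periodic grating
    whose phase drifts with a smooth random field (photographic
    textures are never exactly periodic) plus correlated noise at two
    spatial scales — is perturbed per channel by a weaker independent
    noise field.  Channels are therefore strongly correlated, as in
    colorized texture photographs where color is painted over a single
    gray-level structure.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    i = np.arange(h, dtype=np.float64)[:, None]
    j = np.arange(w, dtype=np.float64)[None, :]

    def two_scale_noise() -> np.ndarray:
        fine = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                       sigma=1.0, mode="wrap")
        coarse = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                         sigma=4.0, mode="wrap")
        return 0.7 * fine / fine.std() + 0.7 * coarse / coarse.std()

    theta = rng.uniform(0, np.pi)
    period = rng.uniform(8, 20)
    phase = rng.uniform(0, 2 * np.pi)
    jitter = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                     sigma=6.0, mode="wrap")
    jitter *= 2.0 / jitter.std()
    base = (spec.amplitude
            * np.sin(2 * np.pi * (i * np.cos(theta) + j * np.sin(theta))
                     / period + phase + jitter)
            + two_scale_noise())
    out = np.empty((h, w, spec.depth))
    for k in range(spec.depth):
        out[:, :, k] = base + 0.35 * two_scale_noise()
    return out


def generate_fixture(spec: FixtureSpec) -> ColorImage:
    """Materialize a fixture; deterministic for non-composite kinds."""
    h, w, d = spec.height, spec.width, spec.depth
    if spec.kind == "constant":
        px = np.full((h, w, d), spec.value, dtype=np.float64)
    elif spec.kind == "checkerboard":
        half = max(spec.period // 2, 1)
        i = np.arange(h)[:, None] // half
        j = np.arange(w)[None, :] // half
        lo, hi = spec.levels
        px = np.where((i + j) % 2 == 0, lo, hi)[:, :, None].repeat(d, axis=2)
        px = px.astype(np.float64)
    elif spec.kind == "sinusoidal":
        px = (spec.amplitude
              * _sinusoid_2d(h, w, spec.period)[:, :, None].repeat(d, axis=2))
    else:  # composite
        px = _composite_texture(spec)
    return ColorImage(px, space="generic")
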
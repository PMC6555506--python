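"""Synthetic test images: bright spheres on a dark background, plus noise.

The generator places non-overlapping spheres by rejection sampling, paints
them at the foreground intensity, smooths the edges with a small Gaussian
(so the integrand is smooth enough for Monte-Carlo estimation), and returns
the exact ground-truth centers and radii.  Gaussian noise is injected at a
requested signal-to-noise ratio defined as
``SNR_dB = 10 * log10(P_signal / P_noise)`` with ``P_signal`` the mean
squared intensity of the clean image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["PhantomSpec", "generate_phantom", "add_gaussian_noise"]


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, ...] = (128, 128, 128)
    n_spheres: int = 20
    radius_range: Tuple[float, float] = (8.0, 12.0)
    min_separation: Optional[float] = None  # default 2.2 * max radius
    foreground: float = 1.0
    background: float = 0.0
    smooth_sigma: float = 1.0
    seed: int = 0
    max_tries: int = 20_000

    def __post_init__(self):
        if self.n_spheres < 0:
            raise ValueError("n_spheres must be non-negative")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("invalid radius_range")
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2D or 3D")

    @property
    def separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 2.2 * self.radius_range[1]


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, pd.DataFrame]:
    """Return ``(volume, truth)``; truth columns are (z,) y, x, r0."""
    rng = np.random.default_rng(spec.seed)
    ndim = len(spec.shape)
    shape = np.asarray(spec.shape, dtype=float)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    tries = 0
    while len(centers) < spec.n_spheres:
        if tries >= spec.max_tries:
            raise RuntimeError(
                f"could not pack {spec.n_spheres} spheres after "
                f"{spec.max_tries} tries"
            )
        tries += 1
        r = rng.uniform(*spec.radius_range)
        margin = r + max(2.0, 2.0 * spec.smooth_sigma)
        if np.any(shape - 1 - 2 * margin <= 0):
            raise RuntimeError("volume too small for the requested spheres")
        c = rng.uniform(margin, shape - 1 - margin)
        if all(
            np.linalg.norm(c - c0) >= spec.separation for c0 in centers
        ):
            centers.append(c)
            radii.append(float(r))

    vol = np.full(spec.shape, spec.background, dtype=np.float64)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int) + 1, np.asarray(spec.shape))
        grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
        dist2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        block = vol[tuple(slice(a, b) for a, b in zip(lo, hi))]
        np.copyto(block, spec.foreground, where=dist2 < r * r)
    if spec.smooth_sigma > 0:
        vol = ndi.gaussian_filter(vol, sigma=spec.smooth_sigma)

    axis_names = ["z", "y", "x"][-ndim:]
    truth = pd.DataFrame(
        np.column_stack([np.asarray(centers).reshape(len(centers), ndim), radii])
        if centers
        else np.empty((0, ndim + 1)),
        columns=[*axis_names, "r0"],
    )
    return vol, truth


def add_gaussian_noise(
    image: np.ndarray, snr_db: float, seed: int = 0, clamp: bool = False
) -> np.ndarray:
    """Add zero-mean Gaussian noise scaled to the requested SNR (dB).

    ``sigma**2 = mean(I**2) / 10**(snr_db / 10)``.  Clamping to [0, 1] is
    off by default so the realized SNR stays exact.
    """
    image = np.asarray(image, dtype=np.float64)
    p_signal = float(np.mean(image**2))
    if p_signal <= 0:
        raise ValueError("SNR undefined for an all-zero image")
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, sigma, size=image.shape)
    if clamp:
        noisy = np.clip(noisy, 0.0, 1.0)
    return noisy
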
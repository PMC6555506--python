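"""Reproducible benchmark experiments built from the library primitives.

These drive the validation studies: the closed-form energy sweep, the
Monte-Carlo error-scaling law, analytic-vs-numeric gradient agreement,
parameter recovery on an isolated blob, and end-to-end detection quality on
sphere phantoms (optionally under Gaussian noise at a fixed SNR).
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from . import model, sampling
from .evaluation import evaluate_detections
from .evolution import EvolutionConfig, evolve_snake
from .model import Snake, WeightProfile
from .phantoms import PhantomSpec, add_gaussian_noise, generate_phantom
from .pipeline import PipelineConfig, detect
from .sampling import SamplingConfig

log = logging.getLogger(__name__)

RHO3 = 2.0 ** (-1.0 / 3.0)


def voxelized_blob(shape: int, r0: float, center) -> np.ndarray:
    """Sharp binary blob ``1 + sgn(r0 - r)`` (intensities 0/2) on a grid."""
    grids = np.ogrid[tuple(slice(0, shape) for _ in center)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return 1.0 + np.sign(r0 - r)


def smoothed_blob(shape: int, r0: float, center, sigma: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, shape) for _ in center)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return ndi.gaussian_filter((r < r0).astype(np.float64), sigma)


def closed_form_sweep(
    r0: float = 10.0,
    shape: int = 96,
    factors: Tuple[float, ...] = (0.6, 0.9, 1.0, 1.1, 2 ** (1 / 3), 1.5),
    delta_R: float = 0.2,
    n_alignments: int = 4,
    seed: int = 7,
) -> List[Tuple[float, float, float]]:
    """Discrete energy vs the closed-form sphere-blob energy.

    The discrete energy is averaged over a few random sub-voxel grid
    alignments so lattice-resonance noise does not mask the model
    agreement; the oracle is the sharp-limit closed form (narrow ramps).
    Returns ``(R, mean discrete energy, closed form)`` triples.
    """
    rng = np.random.default_rng(seed)
    base = (shape - 1) / 2.0
    centers = [base + rng.uniform(-0.5, 0.5, 3) for _ in range(n_alignments)]
    images = [(c, voxelized_blob(shape, r0, c)) for c in centers]
    prof = WeightProfile(delta_R=delta_R, ndim=3)
    out = []
    for f in factors:
        R = f * r0
        vals = [
            model.discrete_energy(img, Snake.from_center_radius(c, R), prof)
            for c, img in images
        ]
        closed = model.closed_form_blob_energy(R, r0) / (2.0 * R) ** 3
        out.append((R, float(np.mean(vals)), float(closed)))
    return out


def mc_rmse_slope(
    sample_counts: Tuple[int, ...] = (1_000, 10_000, 100_000),
    n_seeds: int = 50,
    r0: float = 10.0,
    sigma: float = 4.0,
    seed: int = 0,
) -> Tuple[float, List[float]]:
    """Log-log slope of the MC-energy RMSE (vs the grid oracle) in N.

    Uses a heavily smoothed blob so the integrand satisfies the smoothness
    assumption of Monte-Carlo estimation; expected slope is -1/2.
    """
    center = (31.2, 31.6, 31.9)
    img = smoothed_blob(64, r0, center, sigma)
    prof = WeightProfile(delta_R=4.0, ndim=3)
    snake = Snake.from_center_radius(center, 2 ** (1 / 3) * r0)
    e_grid = model.discrete_energy(img, snake, prof)
    rmses = []
    for ns in sample_counts:
        vals = np.array(
            [
                sampling.mc_energy(
                    img, snake, prof, SamplingConfig(n_samples=ns, seed=seed + k)
                )
                for k in range(n_seeds)
            ]
        )
        rmses.append(float(np.sqrt(np.mean((vals - e_grid) ** 2))))
    slope = float(np.polyfit(np.log(sample_counts), np.log(rmses), 1)[0])
    return slope, rmses


def gradient_agreement(
    n_snakes: int = 100, seed: int = 42, step: float = 1e-3
) -> float:
    """Worst relative deviation between analytic and FD gradients."""
    rng = np.random.default_rng(seed)
    img = ndi.gaussian_filter(rng.random((48, 48, 48)), 2.0)
    img = (img - img.min()) / (img.max() - img.min())
    prof = WeightProfile(delta_R=4.0, ndim=3)
    worst = 0.0
    for _ in range(n_snakes):
        s = Snake.from_center_radius(rng.uniform(15, 33, 3), rng.uniform(9, 14))
        g = model.energy_gradient(img, s, prof)
        fd = _fd_gradient(img, s, prof, step)
        rel = np.abs(g - fd) / np.maximum(np.abs(fd), 1e-9)
        worst = max(worst, float(rel.max()))
    return worst


def _fd_gradient(img, s, prof, h):
    out = [
        (
            model.discrete_energy(img, Snake(s.px + h, s.qx, s.cross), prof)
            - model.discrete_energy(img, Snake(s.px - h, s.qx, s.cross), prof)
        )
        / (2 * h),
        (
            model.discrete_energy(img, Snake(s.px, s.qx + h, s.cross), prof)
            - model.discrete_energy(img, Snake(s.px, s.qx - h, s.cross), prof)
        )
        / (2 * h),
    ]
    for a in range(s.cross.size):
        d = np.zeros(s.cross.size)
        d[a] = h
        out.append(
            0.5
            * (
                model.discrete_energy(img, Snake(s.px, s.qx, s.cross + d), prof)
                - model.discrete_energy(img, Snake(s.px, s.qx, s.cross - d), prof)
            )
            / (2 * h)
        )
    return np.array(out)


def parameter_recovery(
    n_trials: int = 100,
    r0: float = 10.0,
    seed: int = 11,
    n_samples: int = 10_000,
) -> float:
    """Fraction of perturbed initializations that recover the blob.

    Success: converged inner radius ``rho * R`` within 10% of ``r0`` and
    center within 1 voxel of the true center.  Initializations are drawn
    with center offsets up to ``0.75 r0`` and radii in
    ``[0.8, 1.6] * 2**(1/3) r0``.
    """
    center = np.array([31.7, 31.4, 31.2])
    img = smoothed_blob(64, r0, center, 1.0)
    prof = WeightProfile(delta_R=4.0, ndim=3)
    scfg = SamplingConfig(n_samples=n_samples, seed=seed)
    ecfg = EvolutionConfig()
    rng = np.random.default_rng(seed)
    hits = 0
    for k in range(n_trials):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        off = u * 0.75 * r0 * rng.random() ** (1 / 3)
        R = rng.uniform(0.8, 1.6) * 2 ** (1 / 3) * r0
        s = Snake.from_center_radius(center + off, R, index=k)
        final = evolve_snake(img, s, prof, ecfg, scfg).final_snake()
        if (
            np.linalg.norm(final.center - center) <= 1.0
            and abs(RHO3 * final.radius - r0) / r0 <= 0.10
        ):
            hits += 1
    return hits / n_trials


def phantom_f_measure(
    seed: int,
    snr_db: Optional[float] = None,
    noise_seed: Optional[int] = None,
    shape: Tuple[int, int, int] = (128, 128, 128),
    n_spheres: int = 20,
    radius_range: Tuple[float, float] = (8.0, 12.0),
    r0: float = 12.0,
    n_samples: int = 10_000,
    presmooth_sigma: float = 0.0,
) -> float:
    """End-to-end detection F-measure on one sphere phantom."""
    spec = PhantomSpec(
        shape=shape, n_spheres=n_spheres, radius_range=radius_range, seed=seed
    )
    vol, truth = generate_phantom(spec)
    if snr_db is not None:
        vol = add_gaussian_noise(
            vol, snr_db, seed=noise_seed if noise_seed is not None else seed + 100
        )
    cfg = PipelineConfig(
        r0=r0,
        profile=WeightProfile(delta_R=4.0, ndim=3),
        evolution=EvolutionConfig(),
        sampling=SamplingConfig(
            n_samples=n_samples, seed=seed, presmooth_sigma=presmooth_sigma
        ),
    )
    result = detect(vol, cfg)
    report = evaluate_detections(
        result.centers(),
        truth[["z", "y", "x"]].to_numpy(),
        max_dist=float(truth["r0"].mean()),
    )
    f = report.f_measure if report.f_measure is not None else 0.0
    log.info(
        "phantom seed=%s snr=%s: F=%.3f counts=%s", seed, snr_db, f, result.counts
    )
    return float(f)
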
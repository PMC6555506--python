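"""Gradient-descent contour evolution with a decaying learning rate.

Each snake follows ``p <- p - eps * dE/dp`` (and likewise ``q``) with
``eps = eps0 / n`` at iteration ``n`` until the largest parameter update
falls below ``step_tol``, the iteration cap is reached, or the contour
degenerates (radius below the admissible minimum, or center leaving the
image domain).  The cross-axis coordinates stay shared between ``p`` and
``q``, preserving collinearity.

Populations evolve under an order-independent, data-parallel contract: the
Monte-Carlo sample stream of a snake depends only on the global seed, the
snake's own index, and its iteration number, so the ``serial`` backend
(one snake at a time) and the ``vectorized`` backend (lockstep batches)
produce element-wise identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from . import model, sampling
from .model import Snake, WeightProfile
from .sampling import SamplingConfig

__all__ = ["EvolutionConfig", "SnakeTrajectory", "evolve_snake", "evolve_population"]

_TINY_GRAD = 1e-15


@dataclass(frozen=True)
class EvolutionConfig:
    """Gradient-descent settings.

    epsilon0 : base learning rate.  The default is calibrated so that a
        snake sitting on a unit-contrast blob in a [0, 1]-normalized image
        takes first steps of roughly half a voxel; the literal string
        ``"auto"`` instead scales it per snake so the first-iteration step
        is exactly ``first_step_target`` voxels.
    max_iters : iteration cap.
    step_tol : convergence threshold on the largest parameter update
        (voxels).
    backend : ``"serial"`` or ``"vectorized"``.
    r_min : minimum admissible radius; defaults to the profile's.
    """

    epsilon0: Union[float, str] = 250.0
    max_iters: int = 400
    step_tol: float = 1e-3
    backend: str = "vectorized"
    first_step_target: float = 0.5
    r_min: Optional[float] = None

    def __post_init__(self):
        if isinstance(self.epsilon0, str):
            if self.epsilon0 != "auto":
                raise ValueError("epsilon0 must be a positive number or 'auto'")
        elif self.epsilon0 <= 0:
            raise ValueError("epsilon0 must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.step_tol <= 0:
            raise ValueError("step_tol must be positive")
        if self.backend not in ("serial", "vectorized"):
            raise ValueError("backend must be 'serial' or 'vectorized'")


@dataclass
class SnakeTrajectory:
    """Per-iteration history of one snake.

    Row ``i`` of ``centers``/``radii`` is the configuration after ``i``
    updates (row 0 is the initial state); ``energies[i]`` and ``steps[i]``
    are the energy measured before update ``i`` and the magnitude of that
    update (``nan`` in row 0).
    """

    centers: np.ndarray
    radii: np.ndarray
    energies: np.ndarray
    steps: np.ndarray
    status: str
    n_iters: int
    index: Optional[int] = None

    def final_snake(self) -> Snake:
        energy = self.energies[-1] if len(self.energies) > 1 else np.nan
        return Snake.from_center_radius(
            self.centers[-1],
            max(self.radii[-1], 1e-9),
            energy=None if np.isnan(energy) else float(energy),
            status=self.status,
            index=self.index,
        )


def evolve_snake(
    image,
    snake: Snake,
    profile: WeightProfile,
    evo_cfg: EvolutionConfig,
    samp_cfg: SamplingConfig,
    snake_index: Optional[int] = None,
) -> SnakeTrajectory:
    """Evolve a single snake; see module docstring for the stopping rules."""
    if snake.index is None and snake_index is not None:
        snake = snake.replace(index=snake_index)
    return _evolve_batch(image, [snake], profile, evo_cfg, samp_cfg)[0]


def evolve_population(
    image,
    snakes: Sequence[Snake],
    profile: WeightProfile,
    evo_cfg: EvolutionConfig,
    samp_cfg: SamplingConfig,
) -> List[SnakeTrajectory]:
    """Evolve every snake independently; output order matches input order.

    Each snake's random stream is keyed by its own ``index`` (falling back
    to its list position), so results do not depend on list order or on the
    backend.
    """
    if len(snakes) == 0:
        raise ValueError("snake population must be non-empty")
    snakes = [
        s if s.index is not None else s.replace(index=i)
        for i, s in enumerate(snakes)
    ]
    if evo_cfg.backend == "serial":
        return [
            _evolve_batch(image, [s], profile, evo_cfg, samp_cfg)[0] for s in snakes
        ]
    return _evolve_batch(image, snakes, profile, evo_cfg, samp_cfg)


def _evolve_batch(
    image,
    snakes: Sequence[Snake],
    profile: WeightProfile,
    evo_cfg: EvolutionConfig,
    samp_cfg: SamplingConfig,
) -> List[SnakeTrajectory]:
    """Lockstep evolution of a batch of snakes (batch of one == serial)."""
    arr = sampling.prepare_image(image, samp_cfg)
    cfg = replace(samp_cfg, presmooth_sigma=0.0)
    grid_mode = cfg.mode == "grid"
    if grid_mode:
        arr = np.asarray(arr, dtype=np.float64)
    ndim = arr.ndim
    k = len(snakes)
    ns = cfg.n_samples
    r_min = evo_cfg.r_min if evo_cfg.r_min is not None else profile.r_min
    shape = np.asarray(arr.shape, dtype=np.float64)

    px = np.array([s.px for s in snakes], dtype=np.float64)
    qx = np.array([s.qx for s in snakes], dtype=np.float64)
    cross = np.stack([s.cross for s in snakes]).astype(np.float64)
    indices = [s.index if s.index is not None else i for i, s in enumerate(snakes)]

    auto = evo_cfg.epsilon0 == "auto"
    eps0 = np.full(k, np.nan if auto else float(evo_cfg.epsilon0))
    active = np.ones(k, dtype=bool)
    status = ["active"] * k
    n_iters = np.zeros(k, dtype=int)

    centers0 = np.concatenate([cross, 0.5 * (px + qx)[:, None]], axis=1)
    traj_centers = [[centers0[i].copy()] for i in range(k)]
    traj_radii = [[0.5 * (qx[i] - px[i])] for i in range(k)]
    traj_energies = [[np.nan] for _ in range(k)]
    traj_steps = [[np.nan] for _ in range(k)]

    for n in range(1, evo_cfg.max_iters + 1):
        act = np.flatnonzero(active)
        if act.size == 0:
            break
        m = act.size
        R = 0.5 * (qx[act] - px[act])
        centers = np.concatenate([cross[act], (0.5 * (px + qx))[act, None]], axis=1)

        if grid_mode:
            energy = np.empty(m)
            grad = np.empty((m, ndim + 1))
            for j, i in enumerate(act):
                state = Snake(px=px[i], qx=qx[i], cross=cross[i], index=indices[i])
                energy[j] = model.discrete_energy(arr, state, profile)
                grad[j] = model.energy_gradient(arr, state, profile)
        else:
            reach = profile.footprint_radius(R)
            offs = np.empty((m, ns, ndim), dtype=np.float32)
            for j, i in enumerate(act):
                rng = sampling.rng_for(cfg.seed, indices[i], n)
                offs[j] = sampling.sample_ball_uniform(
                    ns,
                    float(reach[j]),
                    ndim,
                    rng=rng,
                    radial_bias=cfg.radial_bias,
                    dtype=np.float32,
                )
            scale = sampling.ball_measure(reach, ndim) / ns
            T0, TR, Tr = sampling.batch_terms(arr, offs, centers, R, profile, scale)
            energy = T0 / (2.0 * R) ** ndim
            gpx, gqx, crossg = model.combine_gradient(T0, TR, Tr, R, ndim)
            grad = np.column_stack([gpx, gqx, *crossg])

        if auto:
            fresh = np.isnan(eps0[act])
            if np.any(fresh):
                gmax = np.max(np.abs(grad), axis=1)
                eps0[act[fresh]] = evo_cfg.first_step_target / np.maximum(
                    gmax[fresh], _TINY_GRAD
                )
        eps = eps0[act] / n
        upd = -eps[:, None] * grad
        step = np.max(np.abs(upd), axis=1)

        px[act] += upd[:, 0]
        qx[act] += upd[:, 1]
        cross[act] += upd[:, 2:]

        new_R = 0.5 * (qx[act] - px[act])
        new_centers = np.concatenate([cross[act], (0.5 * (px + qx))[act, None]], axis=1)
        in_domain = np.all(
            (new_centers >= 0.0) & (new_centers <= shape - 1.0), axis=1
        )
        for j, i in enumerate(act):
            traj_centers[i].append(new_centers[j].copy())
            traj_radii[i].append(float(new_R[j]))
            traj_energies[i].append(float(energy[j]))
            traj_steps[i].append(float(step[j]))
            n_iters[i] = n
            if new_R[j] < r_min or not in_domain[j]:
                status[i] = "culled-domain"
                active[i] = False
            elif step[j] < evo_cfg.step_tol:
                status[i] = "converged"
                active[i] = False

    return [
        SnakeTrajectory(
            centers=np.asarray(traj_centers[i]),
            radii=np.asarray(traj_radii[i]),
            energies=np.asarray(traj_energies[i]),
            steps=np.asarray(traj_steps[i]),
            status=status[i],
            n_iters=int(n_iters[i]),
            index=indices[i],
        )
        for i in range(k)
    ]
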
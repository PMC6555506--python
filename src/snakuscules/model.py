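"""Contour geometry, radial weight profile, and image energies.

A snake is a pair of concentric balls (inner radius ``rho * R``, outer
radius ``R``) parameterized by two points ``p`` and ``q`` that lie on the
same line along every axis but the last (x) image axis.  Its energy is the
weighted intensity of the annulus minus the weighted intensity of the core,
normalized by ``(q_x - p_x) ** ndim``; it is minimized when the inner ball
covers a bright blob on a dark background.

The radius ratio ``rho`` is ``2 ** (-1/3)`` in 3D and ``2 ** (-1/2)`` in 2D
so that the core and the annulus have equal measure, which makes the energy
vanish on constant images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "DegenerateSnakeError",
    "WeightProfile",
    "Snake",
    "rho_for_ndim",
    "closed_form_blob_energy",
    "normalized_energy",
    "discrete_energy",
    "energy_gradient",
    "combine_gradient",
    "symmetrizing_exponent",
    "as_array",
]

#: Inner/outer radius ratio giving equal core and annulus measure.
RHO_3D = 2.0 ** (-1.0 / 3.0)
RHO_2D = 2.0 ** (-0.5)

ArrayLike = Union[np.ndarray, float]


class DegenerateSnakeError(ValueError):
    """Raised when a snake is too small for the configured weight profile."""


def rho_for_ndim(ndim: int) -> float:
    if ndim == 3:
        return RHO_3D
    if ndim == 2:
        return RHO_2D
    raise ValueError(f"only 2D and 3D snakes are supported, got ndim={ndim}")


def as_array(image) -> np.ndarray:
    """Return the raw intensity array of ``image`` (ndarray or ImageVolume)."""
    data = getattr(image, "data", image)
    return np.asarray(data, dtype=np.float64)


# ---------------------------------------------------------------------------
# smoothstep ramp
# ---------------------------------------------------------------------------

def _smoothstep(t: ArrayLike) -> ArrayLike:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _smoothstep_deriv(t: ArrayLike) -> ArrayLike:
    t = np.asarray(t, dtype=np.float64)
    inside = (t > 0.0) & (t < 1.0)
    return np.where(inside, 6.0 * t * (1.0 - t), 0.0)


# ---------------------------------------------------------------------------
# weight profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightProfile:
    """Radial weight ``S(r; R)``: negative core, positive annulus, smooth ramps.

    The profile is the difference of two soft ball indicators::

        S(r; R) = g(r; R, delta_R) - B(R) * g(r; rho * R, delta_r)

    where ``g`` drops smoothly from 1 to 0 over a ramp of the given width
    centered on the ball radius, and the core ratio ``B(R)`` is solved in
    closed form so that the d-dimensional radial moment
    ``integral S(r) r^(d-1) dr`` is exactly zero for the current ``R``.
    The transition widths stay fixed while the footprint scales with ``R``.

    Parameters
    ----------
    delta_R : float
        Outer transition width in voxels.  The inner width is tied to it by
        ``delta_r = rho * delta_R``.
    ndim : int
        2 or 3.
    """

    delta_R: float = 4.0
    ndim: int = 3

    def __post_init__(self):
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if self.delta_R <= 0:
            raise ValueError("delta_R must be positive")

    @property
    def rho(self) -> float:
        return rho_for_ndim(self.ndim)

    @property
    def delta_r(self) -> float:
        # delta_R / 2**(1/3) in 3D, delta_R / sqrt(2) in 2D
        return self.rho * self.delta_R

    @property
    def r_min(self) -> float:
        """Smallest admissible snake radius (smaller snakes are culled)."""
        return max(2.0 * self.delta_R, 3.0)

    def footprint_radius(self, R: ArrayLike) -> ArrayLike:
        """Support radius of the weight: ``R + delta_R / 2``."""
        return R + 0.5 * self.delta_R

    def validate_radius(self, R: ArrayLike) -> None:
        if np.any(np.asarray(R) <= self.delta_R):
            raise DegenerateSnakeError(
                f"snake radius must exceed delta_R={self.delta_R}"
            )

    # -- closed-form radial moments of the soft ball indicator --------------

    def _moment(self, s: ArrayLike, w: float) -> ArrayLike:
        """``integral_0^inf g(r; s+w/2 ramp) r^(d-1) dr`` for ramp start s."""
        if self.ndim == 3:
            iramp = w * (s * s / 2.0 + 0.7 * s * w + 4.0 * w * w / 15.0)
            return (s + w) ** 3 / 3.0 - iramp
        iramp = w * (s / 2.0 + 0.35 * w)
        return (s + w) ** 2 / 2.0 - iramp

    def _moment_ds(self, s: ArrayLike, w: float) -> ArrayLike:
        if self.ndim == 3:
            return (s + w) ** 2 - w * (s + 0.7 * w)
        return s + 0.5 * w

    def core_ratio(self, R: ArrayLike) -> ArrayLike:
        """Multiplier ``B(R) = 1 + A(R)`` of the inner soft indicator.

        Solving the zero-moment condition gives the ratio of the outer to
        the inner indicator moment.  Because the inner indicator is an
        exact ``rho``-scaled copy of the outer one (``delta_r = rho *
        delta_R``), that ratio is ``rho**-ndim = 2`` for every ``R``, in
        both 2D and 3D; :meth:`moment_ratio` evaluates the closed-form
        moment quotient explicitly for verification.
        """
        self.validate_radius(R)
        out = np.full(np.shape(R), 2.0)
        return out if out.ndim else 2.0

    def core_ratio_grad(self, R: ArrayLike) -> ArrayLike:
        """``dB/dR``; identically zero for the tied transition widths."""
        self.validate_radius(R)
        out = np.zeros(np.shape(R))
        return out if out.ndim else 0.0

    def moment_ratio(self, R: ArrayLike) -> ArrayLike:
        """Closed-form outer/inner indicator moment quotient (equals 2)."""
        self.validate_radius(R)
        outer = self._moment(R - 0.5 * self.delta_R, self.delta_R)
        inner = self._moment(self.rho * R - 0.5 * self.delta_r, self.delta_r)
        return outer / inner

    def core_amplitude(self, R: ArrayLike) -> ArrayLike:
        """Magnitude ``A(R)`` of the (negative) core weight."""
        return self.core_ratio(R) - 1.0

    # -- the weight and its partial derivatives ------------------------------

    def _soft(self, r: ArrayLike, s: ArrayLike, w: float) -> ArrayLike:
        return 1.0 - _smoothstep((r - s) / w)

    def weight(self, r: ArrayLike, R: ArrayLike) -> ArrayLike:
        """Signed weight ``S(r; R)``; zero for ``r >= R + delta_R / 2``."""
        B = self.core_ratio(R)
        outer = self._soft(r, R - 0.5 * self.delta_R, self.delta_R)
        inner = self._soft(r, self.rho * R - 0.5 * self.delta_r, self.delta_r)
        return outer - B * inner

    def weight_grad_r(self, r: ArrayLike, R: ArrayLike) -> ArrayLike:
        """``dS/dr`` at fixed R."""
        B = self.core_ratio(R)
        to = (r - (R - 0.5 * self.delta_R)) / self.delta_R
        ti = (r - (self.rho * R - 0.5 * self.delta_r)) / self.delta_r
        d_outer = -_smoothstep_deriv(to) / self.delta_R
        d_inner = -_smoothstep_deriv(ti) / self.delta_r
        return d_outer - B * d_inner

    def weight_grad_R(self, r: ArrayLike, R: ArrayLike) -> ArrayLike:
        """Total ``dS/dR`` at fixed r, including the implicit ``dB/dR`` term."""
        B = self.core_ratio(R)
        dB = self.core_ratio_grad(R)
        to = (r - (R - 0.5 * self.delta_R)) / self.delta_R
        ti = (r - (self.rho * R - 0.5 * self.delta_r)) / self.delta_r
        g_inner = 1.0 - _smoothstep(ti)
        d_outer = _smoothstep_deriv(to) / self.delta_R
        d_inner = self.rho * _smoothstep_deriv(ti) / self.delta_r
        return d_outer - dB * g_inner - B * d_inner

    def weight_with_grads(self, r: np.ndarray, R: ArrayLike):
        """Fused ``(S, dS/dr, dS/dR)`` evaluation (single pass over ``r``).

        Equivalent to calling :meth:`weight`, :meth:`weight_grad_r` and
        :meth:`weight_grad_R` but avoids recomputing the ramp coordinates;
        this is the hot path of Monte-Carlo evolution.
        """
        self.validate_radius(R)
        dR, dr, rho = self.delta_R, self.delta_r, self.rho
        B = self.core_ratio(R)
        dB = self.core_ratio_grad(R)
        r = np.asarray(r)
        if r.dtype != np.float64:
            # keep the heavy sample arrays in single precision
            R = np.asarray(R, dtype=r.dtype)
            B = np.asarray(B, dtype=r.dtype)
            dB = np.asarray(dB, dtype=r.dtype)
        to = np.clip((r - (R - 0.5 * dR)) / dR, 0.0, 1.0)
        ti = np.clip((r - (rho * R - 0.5 * dr)) / dr, 0.0, 1.0)
        h_o = to * to * (3.0 - 2.0 * to)
        h_i = ti * ti * (3.0 - 2.0 * ti)
        hp_o = (6.0 / dR) * to * (1.0 - to)
        hp_i = (6.0 / dr) * ti * (1.0 - ti)
        g_i = 1.0 - h_i
        S = (1.0 - h_o) - B * g_i
        Sr = B * hp_i - hp_o
        SR = hp_o - dB * g_i - (B * rho) * hp_i
        return S, Sr, SR


# ---------------------------------------------------------------------------
# snake geometry
# ---------------------------------------------------------------------------

@dataclass
class Snake:
    """One contour, stored as ``p``/``q`` x-coordinates plus shared cross-axes.

    ``cross`` holds the coordinates of all image axes except the last (x)
    axis, in image order — ``(z, y)`` for volumes, ``(y,)`` for 2D images.
    """

    px: float
    qx: float
    cross: np.ndarray
    energy: Optional[float] = None
    status: str = "active"
    index: Optional[int] = None

    def __post_init__(self):
        self.cross = np.atleast_1d(np.asarray(self.cross, dtype=np.float64))
        if not self.qx > self.px:
            raise ValueError("snake requires qx > px (positive radius)")
        if self.cross.size not in (1, 2):
            raise ValueError("cross must hold 1 (2D) or 2 (3D) coordinates")

    @classmethod
    def from_center_radius(
        cls,
        center: Sequence[float],
        radius: float,
        energy: Optional[float] = None,
        status: str = "active",
        index: Optional[int] = None,
    ) -> "Snake":
        center = np.asarray(center, dtype=np.float64)
        if radius <= 0:
            raise ValueError("radius must be positive")
        cx = float(center[-1])
        return cls(
            px=cx - radius,
            qx=cx + radius,
            cross=center[:-1].copy(),
            energy=energy,
            status=status,
            index=index,
        )

    @property
    def ndim(self) -> int:
        return self.cross.size + 1

    @property
    def radius(self) -> float:
        return 0.5 * (self.qx - self.px)

    @property
    def cx(self) -> float:
        return 0.5 * (self.px + self.qx)

    @property
    def center(self) -> np.ndarray:
        return np.concatenate([self.cross, [self.cx]])

    @property
    def p(self) -> np.ndarray:
        return np.concatenate([self.cross, [self.px]])

    @property
    def q(self) -> np.ndarray:
        return np.concatenate([self.cross, [self.qx]])

    def replace(self, **kwargs) -> "Snake":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# closed-form binary-blob oracle
# ---------------------------------------------------------------------------

def closed_form_blob_energy(R: ArrayLike, r0: ArrayLike, ndim: int = 3) -> ArrayLike:
    """Continuous (un-normalized) energy of a concentric sharp-edged blob.

    The blob is ``I(r) = 1 + sgn(r0 - r)``: intensity 2 inside radius ``r0``
    and 0 outside.  In 3D the energy is 0 for ``R < r0``,
    ``-(8/3) pi (R^3 - r0^3)`` while the blob edge lies in the annulus, and
    ``-(8/3) pi r0^3`` once the core contains the blob
    (``R >= 2**(1/3) r0``); the 2D counterparts replace volumes by areas.
    """
    R = np.asarray(R, dtype=np.float64)
    r0 = np.asarray(r0, dtype=np.float64)
    if np.any(R <= 0) or np.any(r0 <= 0):
        raise ValueError("R and r0 must be positive")
    rho = rho_for_ndim(ndim)
    if ndim == 3:
        mid = -(8.0 / 3.0) * np.pi * (R ** 3 - r0 ** 3)
        sat = -(8.0 / 3.0) * np.pi * r0 ** 3
    else:
        mid = -2.0 * np.pi * (R ** 2 - r0 ** 2)
        sat = -2.0 * np.pi * r0 ** 2
    out = np.where(R < r0, 0.0, np.where(rho * R < r0, mid, sat))
    return out if out.ndim else float(out)


def normalized_energy(E_hat: ArrayLike, R: ArrayLike, alpha: float = 3.0) -> ArrayLike:
    """Scale-penalized energy ``E_hat / R**alpha``."""
    if np.any(np.asarray(R) <= 0):
        raise ValueError("R must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    out = np.asarray(E_hat, dtype=np.float64) / np.asarray(R, dtype=np.float64) ** alpha
    return out if out.ndim else float(out)


def symmetrizing_exponent(
    r0: float = 1.0,
    ndim: int = 3,
    alphas: Optional[np.ndarray] = None,
    delta: float = 1e-6,
) -> float:
    """Exponent ``alpha`` that balances the normalized-energy slopes.

    Evaluates one-sided finite-difference slopes of
    ``closed_form_blob_energy(R, r0) / R**alpha`` just below and just above
    the optimum ``R* = r0 / rho`` and returns the ``alpha`` from the
    candidate grid for which the left slope equals minus the right slope.
    """
    if alphas is None:
        alphas = np.arange(0.5, 6.0 + 1e-12, 0.001)
    alphas = np.asarray(alphas, dtype=np.float64)
    rho = rho_for_ndim(ndim)
    r_star = r0 / rho
    h = delta * r0
    eps = 10.0 * h
    R_left = r_star - eps
    R_right = r_star + eps

    def nslope(R_at: float, a: float) -> float:
        e_lo = normalized_energy(
            closed_form_blob_energy(R_at - h, r0, ndim), R_at - h, a
        )
        e_hi = normalized_energy(
            closed_form_blob_energy(R_at + h, r0, ndim), R_at + h, a
        )
        return (e_hi - e_lo) / (2.0 * h)

    resid = np.array(
        [abs(nslope(R_left, a) + nslope(R_right, a)) for a in alphas]
    )
    return float(alphas[int(np.argmin(resid))])


# ---------------------------------------------------------------------------
# discrete (voxel-grid) energy and analytic gradient
# ---------------------------------------------------------------------------

def _footprint(arr: np.ndarray, center: np.ndarray, reach: float):
    """Broadcastable per-axis offsets over the full (unclipped) footprint
    bounding box, plus the intensity block zero-padded outside the domain."""
    ndim = arr.ndim
    offsets = []
    box_lo, box_hi = [], []
    for ax, (c, dim) in enumerate(zip(center, arr.shape)):
        lo = int(np.ceil(c - reach))
        hi = int(np.floor(c + reach))
        if hi < lo:
            return None, None
        box_lo.append(lo)
        box_hi.append(hi)
        shape = [1] * ndim
        shape[ax] = hi - lo + 1
        offsets.append((np.arange(lo, hi + 1, dtype=np.float64) - c).reshape(shape))
    block = np.zeros([hi - lo + 1 for lo, hi in zip(box_lo, box_hi)])
    src, dst = [], []
    for lo, hi, dim in zip(box_lo, box_hi, arr.shape):
        s_lo, s_hi = max(lo, 0), min(hi, dim - 1)
        if s_hi < s_lo:
            return offsets, block  # footprint entirely outside: all zeros
        src.append(slice(s_lo, s_hi + 1))
        dst.append(slice(s_lo - lo, s_hi - lo + 1))
    block[tuple(dst)] = arr[tuple(src)]
    return offsets, block


def _grid_fields(arr, snake, profile):
    R = snake.radius
    profile.validate_radius(R)
    offsets, block = _footprint(arr, snake.center, profile.footprint_radius(R))
    if offsets is None:
        return None
    r = np.sqrt(sum(o * o for o in offsets))
    return offsets, block, r, R


def _balanced_terms(r, R, profile):
    """Soft indicators on the voxel set, with the core ratio re-solved from
    the discrete sums so that ``sum_K S = 0`` holds exactly on the lattice
    (the continuous balance only holds up to quadrature error).  Falls back
    to the analytic ratio for pathologically small cores."""
    g_out = profile._soft(r, R - 0.5 * profile.delta_R, profile.delta_R)
    g_in = profile._soft(
        r, profile.rho * R - 0.5 * profile.delta_r, profile.delta_r
    )
    U = float(g_out.sum())
    V = float(g_in.sum())
    if V < 1e-9:
        B = float(profile.core_ratio(R))
    else:
        B = U / V
    return g_out, g_in, U, V, B


def discrete_energy(image, snake: Snake, profile: WeightProfile) -> float:
    """Exhaustive voxel-grid energy ``(2R)^-d * sum_K S(|k - c|) I(k)``.

    ``K`` is the set of voxels within ``R + delta_R / 2`` of the center;
    voxels outside the image domain contribute zero intensity.  The core
    weight is balanced against the discrete lattice sum, so constant images
    have exactly zero energy at every snake position and size.
    """
    arr = as_array(image)
    _check_dims(arr, snake, profile)
    fields = _grid_fields(arr, snake, profile)
    if fields is None:
        return 0.0
    _, block, r, R = fields
    g_out, g_in, U, V, B = _balanced_terms(r, R, profile)
    P = float((g_out * block).sum())
    Q = float((g_in * block).sum())
    return float((P - B * Q) / (2.0 * R) ** arr.ndim)


def combine_gradient(T0, TR, Tr, R, ndim: int):
    """Assemble ``(dE/dpx, dE/dqx, dE/dcross...)`` from weighted sums.

    ``T0 = sum S I``, ``TR = sum (dS/dR) I`` and ``Tr[a] = sum (dS/dr)
    ((k_a - c_a)/r) I`` for every image axis ``a`` (cross axes first, x
    last), all already carrying the integration measure.  The leading terms
    ``+- d / (qx - px)`` come from differentiating the ``(qx - px)^-d``
    normalization.
    """
    L = 2.0 * np.asarray(R, dtype=np.float64)
    gamma = L ** (-float(ndim))
    Tr_x = Tr[-1]
    gpx = gamma * (ndim / L * T0 - 0.5 * Tr_x - 0.5 * TR)
    gqx = gamma * (-ndim / L * T0 - 0.5 * Tr_x + 0.5 * TR)
    cross = [gamma * (-0.5 * t) for t in Tr[:-1]]
    return gpx, gqx, cross


def energy_gradient(image, snake: Snake, profile: WeightProfile) -> np.ndarray:
    """Analytic gradient of :func:`discrete_energy`.

    Returns ``[dE/dpx, dE/dqx, dE/dp_a ...]`` where the trailing entries are
    the shared cross-axis partials (``dE/dp_a = dE/dq_a``) in image-axis
    order (z, y for 3D; y for 2D).  The implicit dependence of the
    discretely balanced core ratio on the snake parameters is included via
    the quotient rule.
    """
    arr = as_array(image)
    _check_dims(arr, snake, profile)
    ndim = arr.ndim
    fields = _grid_fields(arr, snake, profile)
    if fields is None:
        return np.zeros(ndim + 1)
    offsets, block, r, R = fields
    g_out, g_in, U, V, B = _balanced_terms(r, R, profile)
    balanced = V >= 1e-9

    inv_r = np.where(r > 1e-12, 1.0 / np.maximum(r, 1e-12), 0.0)
    dr = profile.delta_r
    dR = profile.delta_R
    t_out = (r - (R - 0.5 * dR)) / dR
    t_in = (r - (profile.rho * R - 0.5 * dr)) / dr
    # radial derivatives of the soft indicators and their R-derivatives
    out_r = -_smoothstep_deriv(t_out) / dR
    in_r = -_smoothstep_deriv(t_in) / dr
    out_R = _smoothstep_deriv(t_out) / dR
    in_R = profile.rho * _smoothstep_deriv(t_in) / dr

    P = float((g_out * block).sum())
    Q = float((g_in * block).sum())
    P_R = float((out_R * block).sum())
    Q_R = float((in_R * block).sum())
    DP = [float((out_r * o * inv_r * block).sum()) for o in offsets]
    DQ = [float((in_r * o * inv_r * block).sum()) for o in offsets]

    if balanced:
        U_R = float(out_R.sum())
        V_R = float(in_R.sum())
        DU = [float((out_r * o * inv_r).sum()) for o in offsets]
        DV = [float((in_r * o * inv_r).sum()) for o in offsets]
        B_R = (U_R * V - U * V_R) / V**2
        # dB/dc_a = (-DU_a V + U DV_a) / V^2
        B_c = [(-du * V + U * dv) / V**2 for du, dv in zip(DU, DV)]
    else:
        B_R = float(profile.core_ratio_grad(R))
        B_c = [0.0] * ndim

    T0 = P - B * Q
    TR = P_R - B * Q_R - B_R * Q
    # Tr_a is defined so that dT0/dc_a = -Tr_a
    Tr = [dp - B * dq + bc * Q for dp, dq, bc in zip(DP, DQ, B_c)]
    gpx, gqx, cross = combine_gradient(T0, TR, Tr, R, ndim)
    return np.array([gpx, gqx, *cross])


def _check_dims(arr: np.ndarray, snake: Snake, profile: WeightProfile) -> None:
    if arr.ndim != snake.ndim:
        raise ValueError(
            f"snake is {snake.ndim}D but image is {arr.ndim}D"
        )
    if arr.ndim != profile.ndim:
        raise ValueError(
            f"profile is {profile.ndim}D but image is {arr.ndim}D"
        )
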
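"""Equivalent model for the heat deposition in the presence of boiling.

Once tissue exceeds T_boil the vapor bubble cloud reflects most of the
incident beam, a phenomenon no tractable acoustic solver reproduces.
The equivalent model replaces it with a small set of rules: heating is
zeroed inside the cloud B; the fraction of the beam power intercepted
by the cloud (the shielding coefficient, maximized over xy-planes) is
redistributed over a dilated neighborhood H of the cloud with weights
W1 (inverse distance to B), W2 (post-focal shielding) and W3 (source-
proportional when the cloud top is locally convex; on concave tops, a
narrow pre-focal cone of refocused enhancement).  Four calibrated
parameters control it: R_SE, eta_intercept, W_plus and theta_cone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import CartesianGrid
from .heat import AxialPowerProfile, HeatSourceField

__all__ = [
    "BoilingModelParams",
    "BoilingState",
    "boiling_region",
    "shielding_coefficient",
    "enhanced_zone",
    "intercepted_power",
    "cloud_convexity",
    "boiling_weights",
    "boiling_heat_source",
    "compose_total_source",
    "boiling_step",
]

#: Sentinel plane index when the cloud is empty.
NO_PLANE = -1


@dataclass(frozen=True)
class BoilingModelParams:
    """Calibrated knobs of the equivalent boiling model."""

    T_boil: float = 85.0            # degC
    R_SE: float = 2.5e-3            # m, dilation radius of the enhanced zone
    eta_intercept: float = 0.31     # fraction of intercepted power that heats
    W_plus: float = 10.0            # concave-regime cone enhancement
    theta_cone: float = math.pi / 18.0  # rad, cone half-aperture
    postfocal_base_attenuation: bool = False

    def __post_init__(self) -> None:
        if self.R_SE <= 0:
            raise ValueError("R_SE must be positive")
        if not (0.0 <= self.eta_intercept <= 1.0):
            raise ValueError("eta_intercept must lie in [0, 1]")
        if self.W_plus < 1.0:
            raise ValueError("W_plus must be >= 1")
        if not (0.0 < self.theta_cone < math.pi / 2.0):
            raise ValueError("theta_cone must lie in (0, pi/2)")


@dataclass
class BoilingState:
    """Per-step diagnostics of the boiling model."""

    B: np.ndarray             # bubble-cloud mask
    H: np.ndarray             # enhanced-heating zone (dilated cloud)
    r_shield: float
    z_shield: int             # plane index, NO_PLANE if cloud empty
    P_H: float                # redistributed power, W
    convex: bool
    focus: tuple[float, float, float]  # instantaneous focus (m)


def boiling_region(T: np.ndarray, T_boil: float) -> np.ndarray:
    """Grid points strictly above the boiling temperature."""
    return T > T_boil


def shielding_coefficient(
    Q: HeatSourceField | np.ndarray, B: np.ndarray
) -> tuple[float, int]:
    """Maximum over xy-planes of the fraction of deposited power that
    falls inside the cloud; ties resolve to the most proximal plane."""
    Qa = Q.Q if isinstance(Q, HeatSourceField) else Q
    tot = Qa.sum(axis=(0, 1))
    inter = np.where(B, Qa, 0.0).sum(axis=(0, 1))
    ratio = np.divide(inter, tot, out=np.zeros_like(tot), where=tot > 0)
    if not B.any() or ratio.max() <= 0.0:
        return 0.0, NO_PLANE
    z_shield = int(np.argmax(ratio))  # argmax returns the smallest index on ties
    return float(ratio[z_shield]), z_shield


def _ball_offsets_radius(R_SE: float, dx: float) -> float:
    return R_SE / dx


def enhanced_zone(
    B: np.ndarray, R_SE: float, grid: CartesianGrid
) -> np.ndarray:
    """Binary dilation of the cloud with the voxelized Euclidean ball
    {offsets : ||offset|| * dx <= R_SE}, computed via the exact
    Euclidean distance transform."""
    if R_SE < grid.dx:
        raise ValueError("R_SE must be at least one voxel")
    if not B.any():
        return np.zeros_like(B)
    dist = ndimage.distance_transform_edt(~B)
    return dist <= _ball_offsets_radius(R_SE, grid.dx) + 1e-9


def intercepted_power(
    r_shield: float,
    z_shield: int,
    profile: AxialPowerProfile,
    eta_intercept: float,
) -> float:
    """P_H = eta_intercept * r_shield * P(z_shield)."""
    if r_shield <= 0.0 or z_shield == NO_PLANE:
        return 0.0
    return float(eta_intercept * r_shield * profile.P[z_shield])


def cloud_convexity(
    B: np.ndarray, focus_index: tuple[int, int]
) -> bool:
    """Whether the proximal tip of the cloud sits on the focal column:
    the global min z over B must equal the min z over the column
    (x, y) = focus_index.  Raises on an empty cloud."""
    if not B.any():
        raise ValueError("convexity undefined for an empty cloud")
    zmin_global = int(np.flatnonzero(B.any(axis=(0, 1)))[0])
    col = B[focus_index[0], focus_index[1], :]
    if not col.any():
        return False
    return int(np.flatnonzero(col)[0]) == zmin_global


def boiling_weights(
    B: np.ndarray,
    H: np.ndarray,
    Q0: np.ndarray,
    grid: CartesianGrid,
    focus: tuple[float, float, float],
    z_shield: int,
    r_shield: float,
    convex: bool,
    params: BoilingModelParams,
) -> np.ndarray:
    """Combined weight field W1*W2*W3, defined on H \\ B, zero elsewhere.

    W1 = 1 / (Euclidean distance to B in voxel units); W2 = 1 up to
    z_shield and r_shield beyond it; W3 follows the heating regime:
    proportional to the unmodified source Q0 when the cloud top is
    locally convex, otherwise uniform with a W_plus boost inside the
    pre-focal cone of half-aperture theta_cone whose apex sits at the
    instantaneous focus.
    """
    support = H & ~B
    W = np.zeros(B.shape, dtype=np.float64)
    if not support.any():
        return W
    dist = ndimage.distance_transform_edt(~B)
    with np.errstate(divide="ignore"):
        W1 = np.where(support, 1.0 / np.maximum(dist, 1e-12), 0.0)
    W2 = np.ones(B.shape)
    if z_shield != NO_PLANE:
        W2[:, :, z_shield + 1:] = r_shield
    if convex:
        W3 = np.maximum(Q0, 0.0)
    else:
        W3 = np.ones(B.shape)
        xf, yf, zf = focus
        X = grid.x[:, None, None] - xf
        Y = grid.y[None, :, None] - yf
        dz = zf - grid.z[None, None, :]  # positive toward the transducer
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.arctan2(np.sqrt(X * X + Y * Y), dz)
        cone = (dz > 0) & (ang <= params.theta_cone)
        W3[cone] = params.W_plus
    W[support] = (W1 * W2 * W3)[support]
    return W


def boiling_heat_source(
    P_H: float, W: np.ndarray, grid: CartesianGrid
) -> np.ndarray:
    """Distribute P_H over the weight field so the volume integral of
    Q_boil equals P_H exactly."""
    if P_H <= 0.0:
        return np.zeros_like(W)
    total = W.sum()
    if total <= 0.0:
        raise ValueError("all boiling weights are zero but P_H > 0")
    return (P_H / (total * grid.dx**3)) * W


def compose_total_source(
    Q0: np.ndarray,
    B: np.ndarray,
    Q_boil: np.ndarray,
    r_shield: float,
    z_shield: int,
    params: BoilingModelParams,
) -> np.ndarray:
    """Total deposition: the base source with the cloud zeroed, plus the
    redistributed boiling term.  Optionally the base source beyond
    z_shield is attenuated by (1 - r_shield) — off by default, the
    equivalent model accepting the residual double counting."""
    Q = np.where(B, 0.0, Q0)
    if params.postfocal_base_attenuation and z_shield != NO_PLANE:
        Q[:, :, z_shield + 1:] *= 1.0 - r_shield
    return Q + Q_boil


def _bbox_with_margin(B: np.ndarray, margin: int):
    idx = np.argwhere(B)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + margin + 1, B.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def boiling_step(
    T: np.ndarray,
    Q0: np.ndarray,
    profile: AxialPowerProfile,
    grid: CartesianGrid,
    focus: tuple[float, float, float],
    params: BoilingModelParams,
) -> tuple[np.ndarray, BoilingState]:
    """One full boiling-model evaluation: detect the cloud in T, build
    the enhanced zone and the weights (on a cropped box around the
    cloud for speed), and return (Q_total, diagnostics).  With no cloud
    the base source is returned unchanged."""
    B = boiling_region(T, params.T_boil)
    if not B.any():
        return Q0, BoilingState(
            B=B, H=np.zeros_like(B), r_shield=0.0, z_shield=NO_PLANE,
            P_H=0.0, convex=True, focus=focus,
        )
    r_shield, z_shield = shielding_coefficient(Q0, B)
    fi = grid.index_of(focus)
    convex = cloud_convexity(B, (fi[0], fi[1]))
    P_H = intercepted_power(r_shield, z_shield, profile, params.eta_intercept)

    r_vox = int(math.ceil(params.R_SE / grid.dx))
    box = _bbox_with_margin(B, r_vox + 1)
    Bc = B[box]
    dist = ndimage.distance_transform_edt(~Bc)
    Hc = dist <= params.R_SE / grid.dx + 1e-9
    H = np.zeros_like(B)
    H[box] = Hc

    # weights on the cropped box
    support = Hc & ~Bc
    Wc = np.zeros(Bc.shape)
    if support.any() and P_H > 0.0:
        with np.errstate(divide="ignore"):
            W1 = np.where(support, 1.0 / np.maximum(dist, 1e-12), 0.0)
        W2 = np.ones(Bc.shape)
        zs_local = z_shield - box[2].start
        if zs_local < Bc.shape[2] - 1:
            W2[:, :, max(zs_local + 1, 0):] = r_shield
        if convex:
            W3 = np.maximum(Q0[box], 0.0)
        else:
            W3 = np.ones(Bc.shape)
            xf, yf, zf = focus
            X = grid.x[box[0]][:, None, None] - xf
            Y = grid.y[box[1]][None, :, None] - yf
            dz = zf - grid.z[box[2]][None, None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                ang = np.arctan2(np.sqrt(X * X + Y * Y), dz)
            W3[(dz > 0) & (ang <= params.theta_cone)] = params.W_plus
        Wc = np.where(support, W1 * W2 * W3, 0.0)

    Q_total = np.where(B, 0.0, Q0)
    if params.postfocal_base_attenuation and z_shield != NO_PLANE:
        Q_total[:, :, z_shield + 1:] *= 1.0 - r_shield
    wsum = Wc.sum()
    if P_H > 0.0 and wsum > 0.0:
        Q_total[box] += (P_H / (wsum * grid.dx**3)) * Wc
    state = BoilingState(
        B=B, H=H, r_shield=r_shield, z_shield=z_shield, P_H=P_H,
        convex=convex, focus=focus,
    )
    return Q_total, state
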
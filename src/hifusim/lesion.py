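"""Thermal dose accumulation, lesion extraction and morphometry.

Damage follows the CEM43 thermal dose D = integral of 0.5^(43 - T) dt
(seconds of equivalent heating at 43 degC), with the single base 0.5
applied at all temperatures.  Voxels with D >= 14 400 s are destroyed;
the lesion is the largest 6-connected component of that mask and its
sizes are bounding-box extents.  The cumulative boiling mask doubles as
the simulated analogue of the hyperechoic mark (HEM) visible on B-mode
imaging; its area is measured in the central xz plane through the
focus, which corresponds to the imaging plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bioheat import DOSE_THRESHOLD, ThermalState
from .grid import CartesianGrid

__all__ = [
    "LesionMetrics",
    "accumulate_dose",
    "lesion_mask",
    "largest_component",
    "lesion_extents",
    "boiling_onset_time",
    "hem_area_xz",
    "measure_lesion",
]


@dataclass
class LesionMetrics:
    """Morphometry of a simulated lesion."""

    extent_x: float           # mm
    extent_y: float           # mm
    extent_z: float           # mm
    volume: float             # mm^3
    boiling_onset_time: float | None  # s
    hem_area_xz: float        # mm^2
    mask: np.ndarray


def accumulate_dose(state: ThermalState, dt: float) -> ThermalState:
    """D += dt * 0.5^(43 - T) voxelwise with the post-step temperature.

    (The solver's step already performs this; the standalone operation
    exists for imported temperature histories.)"""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.D += dt * np.exp2(state.T - 43.0)
    return state


def lesion_mask(D: np.ndarray, threshold: float = DOSE_THRESHOLD) -> np.ndarray:
    """Destroyed tissue: D >= threshold (inclusive)."""
    return D >= threshold


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 6-connected component of a boolean volume."""
    if not mask.any():
        return np.zeros_like(mask)
    labels, n = ndimage.label(mask, structure=_STRUCT6)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def lesion_extents(
    mask: np.ndarray, grid: CartesianGrid
) -> tuple[float, float, float]:
    """Bounding-box extents (mm) of the largest connected component:
    (max index - min index + 1) * dx per axis; zeros when empty."""
    comp = largest_component(mask)
    if not comp.any():
        return (0.0, 0.0, 0.0)
    idx = np.argwhere(comp)
    span = idx.max(axis=0) - idx.min(axis=0) + 1
    return tuple(float(s) * grid.dx * 1e3 for s in span)  # type: ignore[return-value]


def boiling_onset_time(
    times: np.ndarray, max_T: np.ndarray, T_boil: float = 85.0
) -> float | None:
    """First crossing of T_boil by the peak temperature, linearly
    interpolated between samples; None if boiling never occurs."""
    times = np.asarray(times, dtype=float)
    max_T = np.asarray(max_T, dtype=float)
    above = max_T > T_boil
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    t0, t1 = times[i - 1], times[i]
    T0, T1 = max_T[i - 1], max_T[i]
    if T1 == T0:
        return float(t1)
    return float(t0 + (T_boil - T0) / (T1 - T0) * (t1 - t0))


def hem_area_xz(
    boiling_mask: np.ndarray,
    grid: CartesianGrid,
    y_index: int | None = None,
    projected: bool = False,
) -> float:
    """Area (mm^2) of the cumulative boiling mask in the central xz
    plane through the focus (one voxel thick along y), the simulated
    analogue of the manually segmented hyperechoic mark.  With
    ``projected`` the mask is collapsed along y instead."""
    if projected:
        plane = boiling_mask.any(axis=1)
    else:
        if y_index is None:
            y_index = boiling_mask.shape[1] // 2
        plane = boiling_mask[:, y_index, :]
    return float(plane.sum()) * (grid.dx * 1e3) ** 2


def measure_lesion(
    state: ThermalState,
    grid: CartesianGrid,
    times: np.ndarray,
    max_T: np.ndarray,
    T_boil: float = 85.0,
    focus_y_index: int | None = None,
) -> LesionMetrics:
    """Extract the lesion and its morphometry from a final state."""
    mask = lesion_mask(state.D)
    ex, ey, ez = lesion_extents(mask, grid)
    bmask = (
        state.cumulative_boiling_mask
        if state.cumulative_boiling_mask is not None
        else np.zeros_like(mask)
    )
    return LesionMetrics(
        extent_x=ex,
        extent_y=ey,
        extent_z=ez,
        volume=float(mask.sum()) * (grid.dx * 1e3) ** 3,
        boiling_onset_time=boiling_onset_time(times, max_T, T_boil),
        hem_area_xz=hem_area_xz(bmask, grid, y_index=focus_y_index),
        mask=mask,
    )
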
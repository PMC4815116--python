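"""Voxel grid and layered media with acoustic and thermal properties.

The simulation domain is a small isotropic Cartesian box placed around the
focus of the therapy transducer.  The propagation axis is ``z``, oriented
from the transducer toward the focus; ``x`` is parallel to the imaging
probe, ``y`` orthogonal to it.  Media are stacked along ``z`` (water /
superficial tissue / liver) and are invariant in ``x`` and ``y``.

Internal units are strictly SI (m, s, kg, W); attenuation is stored in the
field-conventional dB cm^-1 MHz^-y form and converted on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CartesianGrid",
    "MediumProperties",
    "LayeredMedium",
    "build_grid",
    "attenuation_at_frequency",
    "WATER",
    "SUPERFICIAL_TISSUE",
    "LIVER",
]

#: dB -> Np conversion for pressure amplitude.
_DB_TO_NP = np.log(10.0) / 20.0


@dataclass(frozen=True)
class CartesianGrid:
    """Isotropic voxel lattice.

    ``origin`` is the physical coordinate (m) of the *center* of voxel
    (0, 0, 0); voxel ``i`` along an axis has center ``origin + i * dx``.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 3:
            raise ValueError("grid needs at least 3 voxels per axis")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny * self.nz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical center coordinates (m) of the voxels along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.dx * np.arange(n)

    @property
    def x(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis_coords(2)

    def voxel_center(self, i: int, j: int, k: int) -> tuple[float, float, float]:
        ox, oy, oz = self.origin
        return (ox + i * self.dx, oy + j * self.dx, oz + k * self.dx)

    def index_of(self, point: Sequence[float]) -> tuple[int, int, int]:
        """Nearest voxel index of a physical point (exact round-trip for
        voxel centers)."""
        idx = tuple(
            int(round((p - o) / self.dx))
            for p, o in zip(point, self.origin)
        )
        for i, n in zip(idx, self.shape):
            if not (0 <= i < n):
                raise ValueError(f"point {point} outside grid")
        return idx  # type: ignore[return-value]

    def contains(self, point: Sequence[float], strict: bool = False) -> bool:
        """Whether a physical point lies inside the voxel-center extents."""
        for p, o, n in zip(point, self.origin, self.shape):
            lo, hi = o, o + (n - 1) * self.dx
            if strict:
                if not (lo < p < hi):
                    return False
            elif not (lo <= p <= hi):
                return False
        return True


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic and thermal properties of one medium.

    Attenuation follows the power law ``alpha0 * f^y`` with ``alpha0`` in
    dB cm^-1 MHz^-y and ``f`` in MHz.  ``A`` is the absorption-to-
    attenuation ratio: the fraction of the power lost by the wave that is
    converted to heat (the remainder is scattered).
    """

    name: str
    c_s: float        # sound speed, m/s
    rho0: float       # density, kg/m^3
    alpha0: float     # attenuation at 1 MHz, dB cm^-1 MHz^-y
    y: float          # attenuation frequency exponent
    C0: float         # baseline specific heat, J kg^-1 K^-1
    k_t: float        # thermal conductivity, W m^-1 K^-1
    w_b0: float = 0.0  # perfusion rate at zero dose, s^-1
    A: float = 1.0    # absorption / attenuation ratio
    is_tissue: bool = True  # phase-change specific-heat profiles apply

    def __post_init__(self) -> None:
        for attr in ("c_s", "rho0", "C0", "k_t"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        if self.alpha0 < 0 or self.w_b0 < 0:
            raise ValueError("alpha0 and w_b0 must be non-negative")
        if not (0.0 < self.A <= 1.0):
            raise ValueError("A must lie in (0, 1]")

    @property
    def impedance(self) -> float:
        return self.rho0 * self.c_s


def attenuation_at_frequency(medium: MediumProperties, f_mhz: float) -> float:
    """Pressure attenuation coefficient in Np/m at frequency ``f_mhz``.

    ``alpha0 * f^y`` (dB/cm) converted with ln(10)/20 Np per dB and 100
    cm per m.  The coefficient applies to pressure amplitude, so intensity
    decays with ``2 * alpha``.
    """
    if f_mhz <= 0:
        raise ValueError("frequency must be positive")
    alpha_db_cm = medium.alpha0 * f_mhz ** medium.y
    return alpha_db_cm * _DB_TO_NP * 100.0


# Medium properties for the three-layer stack (water / superficial
# tissue / liver).  Liver thermal values are the tabulated rabbit/bovine
# liver parameters; water and superficial-tissue thermal values are
# standard textbook figures since only liver is heated appreciably.
WATER = MediumProperties(
    name="water", c_s=1447.0, rho0=1000.0, alpha0=2.2e-3, y=2.0,
    C0=4180.0, k_t=0.60, w_b0=0.0, A=1.0, is_tissue=False,
)
SUPERFICIAL_TISSUE = MediumProperties(
    name="superficial_tissue", c_s=1547.0, rho0=1214.0, alpha0=0.62, y=1.27,
    C0=3600.0, k_t=0.50, w_b0=0.018, A=0.37, is_tissue=True,
)
LIVER = MediumProperties(
    name="liver", c_s=1614.0, rho0=996.0, alpha0=0.37, y=1.27,
    C0=3700.0, k_t=0.55, w_b0=0.018, A=0.37, is_tissue=True,
)


@dataclass
class LayeredMedium:
    """Stack of media along z, each occupying ``[z_start, z_end)`` in the
    global coordinate frame (z = 0 at the transducer apex).

    Intervals must be contiguous and ordered; the last layer extends to
    +inf so that any grid position is covered.
    """

    boundaries: list[float] = field(default_factory=list)  # interface z (m), ascending
    media: list[MediumProperties] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.media) == 0:
            raise ValueError("at least one medium required")
        if len(self.boundaries) != len(self.media) - 1:
            raise ValueError("need exactly one boundary between consecutive media")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly ascending")

    @classmethod
    def single(cls, medium: MediumProperties) -> "LayeredMedium":
        return cls(boundaries=[], media=[medium])

    def layer_index(self, z: float | np.ndarray) -> np.ndarray:
        return np.searchsorted(np.asarray(self.boundaries), z, side="right")

    def medium_at(self, z: float) -> MediumProperties:
        return self.media[int(self.layer_index(z))]

    def property_profile(self, z: np.ndarray, attr: str) -> np.ndarray:
        """Per-plane value of a scalar medium property along z."""
        idx = self.layer_index(z)
        vals = np.array([getattr(m, attr) for m in self.media], dtype=float)
        return vals[idx]

    def property_volume(self, grid: CartesianGrid, attr: str) -> np.ndarray:
        """Per-voxel value of a scalar property (piecewise constant in z,
        independent of x and y), broadcast to the grid shape."""
        prof = self.property_profile(grid.z, attr)
        return np.broadcast_to(prof[None, None, :], grid.shape).copy()

    def tissue_mask(self, grid: CartesianGrid) -> np.ndarray:
        idx = self.layer_index(grid.z)
        flags = np.array([m.is_tissue for m in self.media], dtype=bool)
        return np.broadcast_to(flags[idx][None, None, :], grid.shape).copy()

    def attenuation_profile(self, z: np.ndarray, f_mhz: float) -> np.ndarray:
        """Pressure attenuation (Np/m) per z position."""
        idx = self.layer_index(z)
        vals = np.array(
            [attenuation_at_frequency(m, f_mhz) for m in self.media], dtype=float
        )
        return vals[idx]

    def cumulative_attenuation(self, z: float, f_mhz: float) -> float:
        """Integral of the attenuation coefficient (Np) from z=0 to z."""
        total = 0.0
        lo = 0.0
        edges = list(self.boundaries) + [np.inf]
        for medium, hi in zip(self.media, edges):
            if z <= lo:
                break
            seg = min(z, hi) - lo
            total += attenuation_at_frequency(medium, f_mhz) * seg
            lo = hi
        return total

    def cumulative_slowness(self, z: float) -> float:
        """Integral of 1/c (s) from z=0 to z (straight-ray travel time
        per unit axial distance)."""
        total = 0.0
        lo = 0.0
        edges = list(self.boundaries) + [np.inf]
        for medium, hi in zip(self.media, edges):
            if z <= lo:
                break
            seg = min(z, hi) - lo
            total += seg / medium.c_s
            lo = hi
        return total


def build_grid(
    nx: int,
    ny: int,
    nz: int,
    dx: float,
    focus_position: Sequence[float],
    focus_index: Sequence[int] | None = None,
) -> CartesianGrid:
    """Build a grid positioned so that ``focus_position`` falls on the
    voxel with index ``focus_index``.

    By default the focus is centered laterally and placed at 60 % of the
    z extent, leaving more room downstream of the focus than upstream.
    The focus must lie strictly inside the grid.
    """
    if min(nx, ny, nz) < 3:
        raise ValueError("grid needs at least 3 voxels per axis")
    if dx <= 0:
        raise ValueError("dx must be positive")
    if focus_index is None:
        focus_index = (nx // 2, ny // 2, int(round(0.6 * (nz - 1))))
    fi = tuple(int(i) for i in focus_index)
    for i, n in zip(fi, (nx, ny, nz)):
        if not (0 < i < n - 1):
            raise ValueError("focus must lie strictly inside the grid")
    origin = tuple(float(p) - i * dx for p, i in zip(focus_position, fi))
    grid = CartesianGrid(nx=nx, ny=ny, nz=nz, dx=dx, origin=origin)  # type: ignore[arg-type]
    if not grid.contains(focus_position, strict=True):
        raise ValueError("focus outside grid interior")
    return grid
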
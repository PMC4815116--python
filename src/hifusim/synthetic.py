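"""Analytic stand-in beams for fast tests and experiments.

A separable Gaussian focal envelope with plane-wave intensity is a
crude but instantaneous substitute for the Rayleigh/angular-spectrum
beam: it has a realistic focal-spot scale and a well-defined axial
power profile with closed forms, which makes it convenient for oracle
checks and for small-grid simulations of the thermal and boiling
machinery.
"""

from __future__ import annotations

import numpy as np

from .beam import AcousticField
from .grid import CartesianGrid, LayeredMedium

__all__ = ["synthetic_focal_beam", "attenuated_plane_wave"]


def synthetic_focal_beam(
    grid: CartesianGrid,
    media: LayeredMedium,
    peak_pressure: float,
    sigma_lateral: float,
    sigma_axial: float,
    focus: tuple[float, float, float],
    frequency: float = 3.0e6,
) -> AcousticField:
    """Separable Gaussian pressure envelope with plane-wave intensity
    I_z = |p|^2 / (2 rho c), I_x = I_y = 0."""
    if sigma_lateral <= 0 or sigma_axial <= 0:
        raise ValueError("sigmas must be positive")
    xf, yf, zf = focus
    X = (grid.x - xf)[:, None, None]
    Y = (grid.y - yf)[None, :, None]
    Z = (grid.z - zf)[None, None, :]
    p = peak_pressure * np.exp(
        -(X * X + Y * Y) / (2.0 * sigma_lateral**2)
        - Z * Z / (2.0 * sigma_axial**2)
    )
    rho = media.property_profile(grid.z, "rho0")[None, None, :]
    c = media.property_profile(grid.z, "c_s")[None, None, :]
    I = np.zeros((3,) + grid.shape)
    I[2] = p * p / (2.0 * rho * c)
    return AcousticField(
        grid=grid, frequency=frequency, p_amp=p.astype(np.complex128), I=I
    )


def attenuated_plane_wave(
    grid: CartesianGrid,
    media: LayeredMedium,
    p0: float,
    frequency: float = 3.0e6,
) -> AcousticField:
    """Plane wave filling the whole box with per-layer exponential
    amplitude decay; its axial power profile has the closed form
    P(z) = P(0) exp(-2 alpha z) in a homogeneous medium."""
    z = grid.z
    att = np.array(
        [media.cumulative_attenuation(zi, frequency / 1e6) for zi in z]
    )
    att -= att[0]
    amp = p0 * np.exp(-att)
    p = np.broadcast_to(amp[None, None, :], grid.shape).astype(np.complex128).copy()
    rho = media.property_profile(z, "rho0")[None, None, :]
    c = media.property_profile(z, "c_s")[None, None, :]
    I = np.zeros((3,) + grid.shape)
    I[2] = np.abs(p) ** 2 / (2.0 * rho * c)
    return AcousticField(grid=grid, frequency=frequency, p_amp=p, I=I)
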
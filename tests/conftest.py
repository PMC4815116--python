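"""Shared fixtures: small grids, media stacks and fast synthetic setups."""

from __future__ import annotations

import numpy as np
import pytest

from hifusim.boiling import BoilingModelParams
from hifusim.grid import (
    LIVER,
    WATER,
    CartesianGrid,
    LayeredMedium,
    MediumProperties,
    build_grid,
)
from hifusim.simulate import CircleTrajectory, PulsePlan, SimulationSetup
from hifusim.synthetic import synthetic_focal_beam

FOCUS = (0.0, 0.0, 0.038)


@pytest.fixture(scope="session")
def liver_media() -> LayeredMedium:
    return LayeredMedium.single(LIVER)


@pytest.fixture(scope="session")
def lossless_water() -> MediumProperties:
    return MediumProperties(
        name="water0", c_s=1447.0, rho0=1000.0, alpha0=0.0, y=2.0,
        C0=4180.0, k_t=0.6, is_tissue=False,
    )


@pytest.fixture
def small_grid() -> CartesianGrid:
    """Tiny grid around the focus for cheap field evaluations."""
    return build_grid(11, 11, 9, 0.4e-3, FOCUS)


@pytest.fixture
def sim_grid() -> CartesianGrid:
    """Small thermal-simulation grid (31 x 31 x 41 at 0.4 mm)."""
    return build_grid(31, 31, 41, 0.4e-3, FOCUS)


def make_tiny_setup(
    grid: CartesianGrid,
    media: LayeredMedium,
    peak_mpa: float = 11.0,
    A: float = 0.37,
    sigma_defoc: float = 290e-6,
    perfusion: bool = True,
) -> SimulationSetup:
    """Gaussian-beam setup small enough for sub-second pulse runs."""
    if not perfusion:
        from dataclasses import replace

        media = LayeredMedium(
            boundaries=list(media.boundaries),
            media=[replace(m, w_b0=0.0) for m in media.media],
        )
    field = synthetic_focal_beam(
        grid, media, peak_mpa * 1e6, sigma_lateral=0.5e-3, sigma_axial=2.0e-3,
        focus=FOCUS,
    )
    field.source_power_watts = 40.0  # nominal; pulses run at this power
    return SimulationSetup(
        grid=grid,
        media=media,
        field=field,
        focus=FOCUS,
        A=A,
        sigma_defoc=sigma_defoc,
        boiling=BoilingModelParams(),
        formulation="plane_wave",
    )


@pytest.fixture
def tiny_setup(sim_grid, liver_media) -> SimulationSetup:
    return make_tiny_setup(sim_grid, liver_media)


@pytest.fixture
def tiny_plan() -> PulsePlan:
    return PulsePlan(duration=3.0, power=40.0, dt=0.04, cooldown=8.0)


@pytest.fixture
def tiny_moving_plan() -> PulsePlan:
    return PulsePlan(
        duration=5.0, power=40.0, dt=0.04, cooldown=8.0,
        trajectory=CircleTrajectory(diameter=1.3e-3, period=1.0),
    )
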
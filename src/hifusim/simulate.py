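"""Pulse and treatment orchestration.

A :class:`SimulationSetup` bundles everything that is fixed for a given
exposure geometry: grid, layered medium, acoustic field, axial power
profile, conservative heat source, bioheat solver and boiling-model
parameters.  :func:`run_pulse` advances the thermal state through one
HIFU pulse (optionally with a circular focus trajectory) plus a
cool-down, rebuilding the heat deposition through the boiling model at
every step where a bubble cloud exists.  :func:`run_treatment` chains
pulses at lateral offsets on a persistent thermal state with cooling
intervals, as in multi-pulse treatments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .beam import AcousticField
from .bioheat import BioheatSolver, SpecificHeatModel, ThermalState
from .boiling import NO_PLANE, BoilingModelParams, boiling_step
from .grid import CartesianGrid, LayeredMedium
from .heat import (
    AxialPowerProfile,
    HeatSourceField,
    apply_absorption_and_defocus,
    axial_power_profile,
    conservative_heat_source,
    plane_wave_heat_source,
    translate_source,
)
from .lesion import LesionMetrics, measure_lesion

__all__ = [
    "CircleTrajectory",
    "PulsePlan",
    "TreatmentPlan",
    "SimulationSetup",
    "PulseResult",
    "run_pulse",
    "run_treatment",
]


@dataclass(frozen=True)
class CircleTrajectory:
    """Circular focus steering in the xy plane."""

    diameter: float         # m
    period: float = 1.0     # s per revolution

    def offset(self, t: float) -> tuple[float, float]:
        if self.diameter <= 0:
            return (0.0, 0.0)
        r = self.diameter / 2.0
        ang = 2.0 * math.pi * t / self.period
        return (r * math.cos(ang), r * math.sin(ang))


@dataclass(frozen=True)
class PulsePlan:
    """One HIFU pulse: duration, acoustic power, time step, optional
    trajectory and post-pulse cool-down before lesion evaluation."""

    duration: float              # s
    power: float                 # W
    dt: float = 0.04             # s
    trajectory: CircleTrajectory | None = None
    cooldown: float = 30.0       # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.power < 0:
            raise ValueError("power must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.cooldown < 0:
            raise ValueError("cooldown must be non-negative")


@dataclass(frozen=True)
class TreatmentPlan:
    """Sequence of pulses at lateral offsets with inter-pulse cooling."""

    pulse: PulsePlan
    offsets: tuple[tuple[float, float], ...]   # m, per pulse
    cooling: float = 22.0                      # s between pulses
    final_cooldown: float = 30.0               # s after the last pulse

    def __post_init__(self) -> None:
        if self.cooling < 0 or self.final_cooldown < 0:
            raise ValueError("cooling times must be non-negative")

    @classmethod
    def hex_group(
        cls,
        pulse: PulsePlan,
        spacing_x: float = 1.8e-3,
        spacing_y: float = 1.6e-3,
        cooling: float = 22.0,
    ) -> "TreatmentPlan":
        """Hexagonally packed 19-pulse group (rows of 3/4/5/4/3) with
        the given nearest-row spacings, centered on the focus."""
        offsets = []
        for row, n in zip((-2, -1, 0, 1, 2), (3, 4, 5, 4, 3)):
            y = row * spacing_y
            xs = (np.arange(n) - (n - 1) / 2.0) * spacing_x
            offsets.extend((float(x), float(y)) for x in xs)
        return cls(pulse=pulse, offsets=tuple(offsets), cooling=cooling)


@dataclass
class SimulationSetup:
    """Exposure geometry plus derived fields, fixed across pulses."""

    grid: CartesianGrid
    media: LayeredMedium
    field: AcousticField
    focus: tuple[float, float, float]
    A: float = 0.37
    sigma_defoc: float = 290e-6
    boiling: BoilingModelParams = dc_field(default_factory=BoilingModelParams)
    heat_model: SpecificHeatModel = dc_field(default_factory=SpecificHeatModel)
    formulation: str = "conservative"   # or "plane_wave"
    solver: BioheatSolver | None = None
    profile: AxialPowerProfile | None = None
    beam_profile: AxialPowerProfile | None = None
    Q0: HeatSourceField | None = None

    def __post_init__(self) -> None:
        if self.solver is None:
            self.solver = BioheatSolver(self.grid, self.media, self.heat_model)
        if self.profile is None:
            # side-flux-compensated box accounting: its -dP/dz is the
            # power absorbed inside the box per layer (feeds Q_cons)
            self.profile = axial_power_profile(self.field)
        if self.beam_profile is None:
            # true beam power through each plane (full footprint); the
            # box profile is only a valid substitute when the beam is
            # fully contained in the box
            if self.field.beam_power is not None:
                self.beam_profile = AxialPowerProfile(
                    z_index=np.arange(self.grid.nz), P=self.field.beam_power
                )
            else:
                self.beam_profile = self.profile
        if self.Q0 is None:
            self.rebuild_source()

    def rebuild_source(self) -> None:
        """(Re)derive Q0 from the field with the current A and sigma."""
        if self.formulation == "plane_wave":
            base = plane_wave_heat_source(self.field, self.media)
        else:
            base = conservative_heat_source(self.profile, self.field)
        self.Q0 = apply_absorption_and_defocus(base, self.A, self.sigma_defoc)

    def with_source_params(
        self, A: float | None = None, sigma_defoc: float | None = None
    ) -> "SimulationSetup":
        """Cheap copy sharing the acoustic field but with different
        absorption ratio / defocusing (heat source is rebuilt)."""
        new = replace(
            self,
            A=self.A if A is None else A,
            sigma_defoc=self.sigma_defoc if sigma_defoc is None else sigma_defoc,
            Q0=None,
        )
        return new

    @property
    def field_power(self) -> float:
        """Source acoustic power the field was computed at."""
        if self.field.source_power_watts is None:
            raise ValueError("field has no recorded source power")
        return self.field.source_power_watts


@dataclass
class PulseResult:
    history: pd.DataFrame
    metrics: LesionMetrics
    state: ThermalState
    onset: float | None


def _cool(
    state: ThermalState,
    solver: BioheatSolver,
    duration: float,
    dt: float,
    times: list[float],
    max_T: list[float],
) -> None:
    for _ in range(int(round(duration / dt))):
        solver.step(state, None, dt)
        times.append(state.t)
        max_T.append(float(state.T.max()))


def run_pulse(
    plan: PulsePlan,
    setup: SimulationSetup,
    state: ThermalState | None = None,
    base_offset: tuple[float, float] = (0.0, 0.0),
    stop_at_onset: bool = False,
    cooldown: float | None = None,
) -> PulseResult:
    """Simulate one pulse (and its cool-down) on the given setup.

    The heat source is scaled linearly to ``plan.power`` relative to the
    power the field was computed at, translated along the trajectory and
    modified by the boiling model whenever a bubble cloud exists.
    """
    solver = setup.solver
    solver.check_dt(plan.dt)
    if state is None:
        state = ThermalState.uniform(setup.grid)
    t_start = state.t
    power_scale = plan.power / setup.field_power
    Q0 = setup.Q0.Q * power_scale
    profile = AxialPowerProfile(
        z_index=setup.beam_profile.z_index,
        P=setup.beam_profile.P * power_scale,
    )
    Q0_field = HeatSourceField(grid=setup.grid, Q=Q0, provenance=setup.formulation,
                               A_applied=True, sigma_defoc=setup.sigma_defoc)
    T_boil = setup.boiling.T_boil
    times: list[float] = [state.t]
    max_T: list[float] = [float(state.T.max())]
    records: list[dict] = []
    n_steps = int(round(plan.duration / plan.dt))
    onset_seen = max_T[0] > T_boil

    for n in range(n_steps):
        t_local = n * plan.dt
        off = (
            plan.trajectory.offset(t_local)
            if plan.trajectory is not None
            else (0.0, 0.0)
        )
        offset = (off[0] + base_offset[0], off[1] + base_offset[1])
        if offset != (0.0, 0.0):
            Qt = translate_source(Q0_field, offset).Q
        else:
            Qt = Q0
        # The boiling model's focus (convexity column, cone apex) is the
        # pulse's nominal focus: the trajectory center, not the
        # instantaneous steering position.  With a moving focus the
        # hottest point always trails the steering position (thermal
        # lag), so an instantaneous reference would misclassify the
        # cloud top as concave at nearly every step.
        focus = (
            setup.focus[0] + base_offset[0],
            setup.focus[1] + base_offset[1],
            setup.focus[2],
        )
        if plan.power > 0 and (state.T > T_boil).any():
            Q_total, bstate = boiling_step(
                state.T, Qt, profile, setup.grid, focus, setup.boiling
            )
        else:
            Q_total, bstate = Qt, None
        solver.step(state, Q_total if plan.power > 0 else None, plan.dt)
        times.append(state.t)
        tmax = float(state.T.max())
        max_T.append(tmax)
        records.append(
            {
                "t": state.t,
                "max_T": tmax,
                "n_cloud": 0 if bstate is None else int(bstate.B.sum()),
                "n_enhanced": 0 if bstate is None else int(bstate.H.sum()),
                "r_shield": 0.0 if bstate is None else bstate.r_shield,
                "z_shield": NO_PLANE if bstate is None else bstate.z_shield,
                "P_H": 0.0 if bstate is None else bstate.P_H,
                "convex": True if bstate is None else bstate.convex,
            }
        )
        if tmax > T_boil and not onset_seen:
            onset_seen = True
            if stop_at_onset:
                break

    if not (stop_at_onset and onset_seen):
        cd = plan.cooldown if cooldown is None else cooldown
        _cool(state, solver, cd, plan.dt, times, max_T)

    times_arr = np.asarray(times) - t_start
    fi = setup.grid.index_of(setup.focus)
    metrics = measure_lesion(
        state, setup.grid, times_arr, np.asarray(max_T),
        T_boil=T_boil, focus_y_index=fi[1],
    )
    history = pd.DataFrame.from_records(records)
    return PulseResult(
        history=history,
        metrics=metrics,
        state=state,
        onset=metrics.boiling_onset_time,
    )


def run_treatment(
    plan: TreatmentPlan, setup: SimulationSetup
) -> tuple[ThermalState, LesionMetrics, pd.DataFrame]:
    """Execute the pulses sequentially on one persistent thermal state;
    temperature and dose carry over, cooling intervals are simulated
    with the source off, and residual bubble clouds from previous
    pulses are not given any special treatment (the cloud is always
    re-derived from the instantaneous temperature)."""
    state = ThermalState.uniform(setup.grid)
    histories = []
    times: list[float] = [0.0]
    max_T: list[float] = [37.0]
    for k, off in enumerate(plan.offsets):
        last = k == len(plan.offsets) - 1
        res = run_pulse(
            plan.pulse,
            setup,
            state=state,
            base_offset=off,
            cooldown=plan.final_cooldown if last else plan.cooling,
        )
        state = res.state
        h = res.history.copy()
        h["pulse"] = k
        histories.append(h)
    fi = setup.grid.index_of(setup.focus)
    metrics = measure_lesion(
        state, setup.grid, np.asarray([0.0]), np.asarray([37.0]),
        T_boil=setup.boiling.T_boil, focus_y_index=fi[1],
    )
    history = pd.concat(histories, ignore_index=True)
    return state, metrics, history
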
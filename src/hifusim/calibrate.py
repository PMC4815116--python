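"""Two-stage calibration of the absorption ratio A and the defocusing
standard deviation sigma_defoc against boiling onset times.

The stationary short pulse and the moving long pulse separate the two
parameters: raising A advances boiling in both, while raising
sigma_defoc mainly delays the stationary pulse because the moving
pulse's energy is already spread by the focus trajectory.  The solver
therefore alternates two 1-D bisections: an inner loop adjusts
sigma_defoc until the stationary onset matches its target, an outer
loop adjusts A against the moving-pulse onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .simulate import PulsePlan, SimulationSetup, run_pulse

__all__ = ["CalibrationResult", "calibrate_A_sigma"]


@dataclass(frozen=True)
class CalibrationResult:
    A: float
    sigma_defoc: float
    onset_stationary: float
    onset_moving: float
    n_runs: int


def _onset(
    setup: SimulationSetup, plan: PulsePlan, A: float, sigma: float
) -> float:
    """Boiling onset of one run, +inf if the pulse never boils."""
    s = setup.with_source_params(A=A, sigma_defoc=sigma)
    res = run_pulse(plan, s, stop_at_onset=True, cooldown=0.0)
    return math.inf if res.onset is None else res.onset


def calibrate_A_sigma(
    setup_stationary: SimulationSetup,
    plan_stationary: PulsePlan,
    setup_moving: SimulationSetup,
    plan_moving: PulsePlan,
    target_stationary: float = 3.0,
    target_moving: float = 8.1,
    A_bounds: tuple[float, float] = (0.2, 0.8),
    sigma_bounds: tuple[float, float] = (0.0, 1.0e-3),
    tol: float = 0.05,
    max_iter: int = 30,
) -> CalibrationResult:
    """Find (A, sigma_defoc) reproducing both onset targets.

    Onset is monotone decreasing in A (more absorbed power) and
    monotone increasing in sigma_defoc (more spread); both facts are
    verified while bracketing and exploited by bisection.  Raises if
    the targets cannot be bracketed within the bounds.
    """
    runs = 0

    def onset_stat(A: float, sig: float) -> float:
        nonlocal runs
        runs += 1
        return _onset(setup_stationary, plan_stationary, A, sig)

    def onset_mov(A: float, sig: float) -> float:
        nonlocal runs
        runs += 1
        return _onset(setup_moving, plan_moving, A, sig)

    def solve_sigma(A: float) -> float:
        """Inner bisection: sigma such that the stationary onset hits
        its target at this A (onset increasing in sigma)."""
        lo, hi = sigma_bounds
        f_lo = onset_stat(A, lo) - target_stationary
        if f_lo > tol:
            # even a perfectly tight focus boils too late at this A
            return lo
        f_hi = onset_stat(A, hi) - target_stationary
        if f_hi < -tol:
            return hi
        if not (f_lo <= 0.0 <= f_hi or f_lo == 0.0):
            if f_lo > 0:
                return lo
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            f = onset_stat(A, mid) - target_stationary
            if abs(f) <= tol:
                return mid
            if f < 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    A_lo, A_hi = A_bounds  # onset decreasing in A: high A -> early onset
    sig_hi = solve_sigma(A_hi)
    f_hi = onset_mov(A_hi, sig_hi) - target_moving
    sig_lo = solve_sigma(A_lo)
    f_lo = onset_mov(A_lo, sig_lo) - target_moving
    if f_hi > tol and f_lo > tol:
        raise ValueError(
            f"moving-pulse onset target {target_moving} s unreachable: "
            f"onset {f_lo + target_moving:.2f} s at A={A_lo}, "
            f"{f_hi + target_moving:.2f} s at A={A_hi}"
        )
    if f_lo < -tol and f_hi < -tol:
        raise ValueError(
            f"moving-pulse onset target {target_moving} s unreachable: "
            "boiling too early over the whole A range"
        )
    if f_lo < f_hi:
        raise ValueError(
            "onset not monotone decreasing in A; cannot bisect"
        )

    A, sigma = A_hi, sig_hi
    for _ in range(max_iter):
        A = 0.5 * (A_lo + A_hi)
        sigma = solve_sigma(A)
        f = onset_mov(A, sigma) - target_moving
        if abs(f) <= tol:
            break
        if f > 0:       # too late -> need more absorption
            A_lo = A
        else:
            A_hi = A
    onset_s = onset_stat(A, sigma)
    onset_m = onset_mov(A, sigma)
    return CalibrationResult(
        A=A, sigma_defoc=sigma, onset_stationary=onset_s,
        onset_moving=onset_m, n_runs=runs,
    )
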
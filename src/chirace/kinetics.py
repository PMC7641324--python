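"""Competitive-inhibition rate laws for the two helicase motors.

The small molecule competes with ATP at the motor's nucleotide-binding site,
so each motor's translocation velocity follows the single-substrate
competitive-inhibition law

    v([ATP], [I]) = v_max · [ATP] / ( Km · (1 + [I]/Ki) + [ATP] )

whose signature is the ATP-dependent IC50 shift, IC50 = Ki · (1 + [ATP]/Km)
(Cheng–Prusoff).  Two (ATP, IC50) observations therefore pin down (Ki, Km)
exactly; :func:`solve_ki_km` inverts that 2×2 system.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence, Tuple

from .params import (
    EnzymeParams,
    Ic50Observation,
    InvalidParameterError,
    MotorKinetics,
    ReactionConditions,
)


class NoSolutionError(ValueError):
    """The two-condition IC50 system is degenerate or unphysical."""


def motor_velocity(kin: MotorKinetics, cond: ReactionConditions) -> float:
    """Translocation velocity (nt/ms) under competitive inhibition.

    Strictly increasing in [ATP], strictly decreasing in [I].  Requires
    ``cond.mode == "kinetic"``: table mode bypasses the rate law entirely.
    """
    if cond.mode != "kinetic":
        raise InvalidParameterError(
            "motor_velocity requires kinetic mode conditions"
        )
    denom = kin.km_atp * (1.0 + cond.inhibitor_uM / kin.ki_inh) + cond.atp_uM
    return kin.v_max * cond.atp_uM / denom


def cheng_prusoff_ic50(kin: MotorKinetics, atp_uM: float) -> float:
    """Closed-form half-inhibition concentration, IC50 = Ki·(1 + [ATP]/Km).

    At [I] = IC50 the rate law returns exactly half its uninhibited value
    at the same ATP concentration.
    """
    if atp_uM < 0:
        raise InvalidParameterError("atp_uM must be >= 0")
    return kin.ki_inh * (1.0 + atp_uM / kin.km_atp)


def solve_ki_km(
    observations: Sequence[Ic50Observation],
) -> Tuple[float, float]:
    """Solve (Ki, Km) from two IC50 measurements at different ATP levels.

    The system IC50_i = Ki·(1 + A_i/Km) for i = 1, 2 has the unique solution

        Km = (IC50_1·A_2 − IC50_2·A_1) / (IC50_2 − IC50_1)
        Ki = IC50_1 / (1 + A_1/Km)

    Raises :class:`NoSolutionError` when the ATP levels coincide, the IC50s
    coincide, or the implied Km is non-positive.
    """
    if len(observations) != 2:
        raise NoSolutionError("exactly two observations are required")
    o1, o2 = observations
    if o1.atp_uM == o2.atp_uM:
        raise NoSolutionError("the two ATP concentrations must differ")
    if o1.ic50_uM == o2.ic50_uM:
        raise NoSolutionError(
            "equal IC50s at different ATP levels admit no competitive solution"
        )
    km = (o1.ic50_uM * o2.atp_uM - o2.ic50_uM * o1.atp_uM) / (
        o2.ic50_uM - o1.ic50_uM
    )
    if km <= 0:
        raise NoSolutionError(f"implied Km = {km:.4g} μM is not positive")
    ki = o1.ic50_uM / (1.0 + o1.atp_uM / km)
    if ki <= 0:
        raise NoSolutionError(f"implied Ki = {ki:.4g} μM is not positive")
    return ki, km


def velocity_ratio(enz: EnzymeParams, cond: ReactionConditions) -> float:
    """RecB:RecD velocity ratio r = v_B/v_D ∈ (0, 1].

    In kinetic mode the ratio comes from the two rate laws; with
    ki_B < ki_D it is strictly decreasing in inhibitor concentration.  In
    table mode it is read from the calibration table.  A ratio above 1
    (RecB outrunning RecD) violates the loop geometry and is rejected.
    """
    if cond.mode == "table":
        if enz.calibration is None:
            raise InvalidParameterError(
                "table mode requires an enzyme calibration table"
            )
        r = enz.calibration.lookup(cond.inhibitor_uM).ratio
    else:
        v_d = motor_velocity(enz.recD, cond)
        if v_d <= 0:
            raise InvalidParameterError("RecD velocity must be positive")
        r = motor_velocity(enz.recB, cond) / v_d
    if r > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"velocity ratio {r:.4g} > 1: RecB may not outrun RecD"
        )
    return min(r, 1.0)


def relative_activity(enz: EnzymeParams, cond: ReactionConditions) -> float:
    """Nuclease activity relative to the drug-free reaction, in [0, 1].

    Solubilization activity is taken proportional to the RecB velocity, so
    the fraction is v_B([I]) / v_B(0): exactly 1 at [I] = 0, exactly 0.5 at
    [I] = IC50, and monotone decreasing in [I].
    """
    kin_cond = dataclasses.replace(cond, mode="kinetic")
    if kin_cond.atp_uM <= 0:
        raise InvalidParameterError("relative_activity requires [ATP] > 0")
    v0 = motor_velocity(enz.recB, dataclasses.replace(kin_cond, inhibitor_uM=0.0))
    return motor_velocity(enz.recB, kin_cond) / v0
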
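"""Core parameter types shared by the kinetics, simulation and inference layers.

Conventions used throughout the package
---------------------------------------
* Positions are 0-based nucleotide distances measured **from the enzyme entry
  end** of the duplex.  The radiolabeled 5' end is always the end distal to
  entry, so a cut at distance ``p`` on a substrate of length ``S`` releases a
  labeled single-stranded fragment of ``S - p`` nucleotides.
* Velocities are in nt/ms.  With the default RecD velocity of 1 nt/ms,
  nucleotide and millisecond scales are numerically interchangeable.
* Concentrations are in μM, times in ms unless a field name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence


class InvalidParameterError(ValueError):
    """A kinetic or geometric parameter violates its physical constraints."""


class CalibrationError(LookupError):
    """An inhibitor concentration is absent from the calibration table."""


class ConfigError(ValueError):
    """A configuration document is malformed (unknown key, bad schema)."""


EntryEnd = Literal["left", "right"]
Mode = Literal["kinetic", "table"]


@dataclass(frozen=True)
class MotorKinetics:
    """Michaelis–Menten constants for one translocase motor under a
    competitive inhibitor.

    Parameters
    ----------
    v_max : float
        Maximal translocation velocity, nt/ms.
    km_atp : float
        Michaelis constant for ATP, μM.
    ki_inh : float
        Competitive inhibition constant for the small molecule, μM.
    """

    v_max: float
    km_atp: float
    ki_inh: float

    def __post_init__(self) -> None:
        for name in ("v_max", "km_atp", "ki_inh"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"MotorKinetics.{name} must be strictly positive, "
                    f"got {getattr(self, name)!r}"
                )


@dataclass(frozen=True)
class ReactionConditions:
    """Solution conditions for one reaction.

    ``mode`` selects how motor velocities are obtained: ``"kinetic"``
    evaluates the competitive-inhibition rate law, ``"table"`` looks the
    velocity ratio and swing advance up in the packaged calibration table.
    """

    atp_uM: float = 5000.0
    inhibitor_uM: float = 0.0
    duration_s: float = 60.0
    mode: Mode = "table"

    def __post_init__(self) -> None:
        if self.atp_uM < 0 or self.inhibitor_uM < 0:
            raise InvalidParameterError("concentrations must be >= 0")
        if not self.duration_s > 0:
            raise InvalidParameterError("duration_s must be > 0")
        if self.mode not in ("kinetic", "table"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Ic50Observation:
    """One measured (ATP concentration, IC50) pair from a nuclease assay."""

    atp_uM: float
    ic50_uM: float

    def __post_init__(self) -> None:
        if not (self.atp_uM > 0 and self.ic50_uM > 0):
            raise InvalidParameterError(
                "Ic50Observation fields must be strictly positive"
            )


@dataclass(frozen=True)
class SwingModel:
    """Timing of the tethered nuclease-domain swing.

    The swing is fast (~1 ms) when triggered by a Chi site and slow
    (~200–300 ms) when triggered by the lead motor stopping at the DNA end;
    during the slow swing RecB keeps translocating, advancing the cut.

    Parameters
    ----------
    tau_chi_ms : float
        Mean swing time after a Chi encounter, ms.
    tau_stop_ms : float
        Mean swing time after the lead motor stops at the DNA end, ms.
    cv : float
        Coefficient of variation of the swing time (Gamma-distributed).
    chi_offset_nt : int
        Nominal cut offset 3' of the Chi octamer, nt (0–6).
    """

    tau_chi_ms: float = 1.0
    tau_stop_ms: float = 250.0
    cv: float = 0.2
    chi_offset_nt: int = 5

    def __post_init__(self) -> None:
        if not (self.tau_chi_ms > 0 and self.tau_stop_ms > 0):
            raise InvalidParameterError("swing times must be > 0")
        if self.cv < 0:
            raise InvalidParameterError("cv must be >= 0")
        if not 0 <= self.chi_offset_nt <= 6:
            raise InvalidParameterError("chi_offset_nt must be in [0, 6]")


@dataclass(frozen=True)
class SubstrateSpec:
    """Geometry of one 5'-end-labeled linear duplex substrate.

    ``chi_cut_from_label`` is the distance (nt) from the labeled end to the
    nominal Chi-dependent cut; ``None`` marks a Chi-less substrate.  The
    labeled end is the end opposite ``entry_end``.
    """

    name: str
    length_nt: int
    entry_end: EntryEnd = "right"
    chi_cut_from_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.length_nt > 0:
            raise InvalidParameterError("length_nt must be > 0")
        if self.entry_end not in ("left", "right"):
            raise InvalidParameterError(f"bad entry_end {self.entry_end!r}")
        if self.chi_cut_from_label is not None and not (
            0 < self.chi_cut_from_label < self.length_nt
        ):
            raise InvalidParameterError(
                "chi_cut_from_label must lie strictly inside the substrate"
            )

    @property
    def has_chi(self) -> bool:
        return self.chi_cut_from_label is not None

    @property
    def chi_status(self) -> str:
        """'chi+' for a Chi-bearing substrate, 'chi0' otherwise."""
        return "chi+" if self.has_chi else "chi0"

    @property
    def chi_cut_from_entry(self) -> Optional[int]:
        """Distance from the entry end to the nominal Chi cut, nt."""
        if self.chi_cut_from_label is None:
            return None
        return self.length_nt - self.chi_cut_from_label


@dataclass(frozen=True)
class CalibrationEntry:
    """Measured (velocity ratio, swing advance) at one inhibitor level."""

    inhibitor_uM: float
    ratio: float
    advance_nt: float

    def __post_init__(self) -> None:
        if self.inhibitor_uM < 0:
            raise InvalidParameterError("inhibitor_uM must be >= 0")
        if not 0 < self.ratio <= 1:
            raise InvalidParameterError("ratio must be in (0, 1]")
        if self.advance_nt < 0:
            raise InvalidParameterError("advance_nt must be >= 0")


class CalibrationTable:
    """Direct inhibitor → (velocity ratio, advance) lookup.

    Table mode is the default for reproducing the published analysis: the
    source experiments report per-concentration fits, not motor velocities.
    """

    def __init__(self, entries: Sequence[CalibrationEntry]):
        if not entries:
            raise InvalidParameterError("calibration table must be non-empty")
        self._entries = {float(e.inhibitor_uM): e for e in entries}
        if len(self._entries) != len(entries):
            raise InvalidParameterError("duplicate inhibitor_uM in calibration")

    @property
    def concentrations_uM(self) -> list[float]:
        return sorted(self._entries)

    def lookup(self, inhibitor_uM: float) -> CalibrationEntry:
        try:
            return self._entries[float(inhibitor_uM)]
        except KeyError:
            raise CalibrationError(
                f"inhibitor concentration {inhibitor_uM} μM not in the "
                f"calibration table (have {self.concentrations_uM})"
            ) from None

    def __contains__(self, inhibitor_uM: float) -> bool:
        return float(inhibitor_uM) in self._entries

    def __iter__(self):
        return iter(self._entries[c] for c in self.concentrations_uM)

    def __eq__(self, other) -> bool:
        return isinstance(other, CalibrationTable) and self._entries == other._entries


@dataclass(frozen=True)
class EnzymeParams:
    """Full parameterization of one helicase–nuclease complex.

    ``p_chi_recognition`` is the probability that a traversed Chi site
    triggers cutting; ``k_sens_uM`` is the half-saturation of the
    inhibitor-induced end-stop sensitization, p_sens = [I]/([I]+k_sens).
    """

    recB: MotorKinetics
    recD: MotorKinetics
    swing: SwingModel = field(default_factory=SwingModel)
    p_chi_recognition: float = 1.0
    k_sens_uM: float = 75.0
    calibration: Optional[CalibrationTable] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_chi_recognition <= 1:
            raise InvalidParameterError("p_chi_recognition must be in [0, 1]")
        if not self.k_sens_uM > 0:
            raise InvalidParameterError("k_sens_uM must be > 0")
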
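"""Packaged default configuration and its strict loader.

The YAML schema mirrors the module boundaries: kinetic constants and the
calibration table (kinetics), swing/sensitization parameters (race), gel and
marker constants (gel), substrate geometry and experiment design
(synthetic).  Unknown keys anywhere in the document are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .params import (
    CalibrationEntry,
    CalibrationTable,
    ConfigError,
    EnzymeParams,
    Ic50Observation,
    InvalidParameterError,
    MotorKinetics,
    SubstrateSpec,
    SwingModel,
)
from .gel import GelParams, Marker, make_marker_ladder

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NoiseModel:
    band_jitter_mm: float = 0.0
    activity_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.band_jitter_mm < 0 or self.activity_cv < 0:
            raise InvalidParameterError("noise magnitudes must be >= 0")


@dataclass(frozen=True)
class NucleaseAssaySettings:
    """Generator settings for the standard-condition solubilization assay."""

    atp_uM: float
    ic50_uM: float
    concentrations_uM: tuple
    replicates: int
    noise_cv: float


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to generate and analyze one in-silico study."""

    enzyme: EnzymeParams
    gel: GelParams
    marker_lengths_nt: tuple
    substrate_lengths_nt: tuple
    chi_cut_from_label_nt: int
    ic50_observations: tuple
    nuclease_assay: NucleaseAssaySettings
    concentrations_uM: tuple
    n_molecules: int
    noise: NoiseModel
    seed: int

    def markers(self) -> List[Marker]:
        return make_marker_ladder(self.marker_lengths_nt, self.gel)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _motor(block: dict, where: str) -> MotorKinetics:
    _check_keys(block, {"v_max", "km_atp", "ki_inh"}, where)
    try:
        return MotorKinetics(**block)
    except (TypeError, InvalidParameterError) as exc:
        raise ConfigError(f"bad motor kinetics in {where}: {exc}") from exc


def parse_config(doc: dict) -> RunConfig:
    """Validate a configuration document and build a :class:`RunConfig`."""
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    top_keys = {
        "schema_version",
        "kinetics",
        "swing",
        "enzyme",
        "calibration",
        "gel",
        "markers_nt",
        "substrates",
        "ic50_observations",
        "nuclease_assay",
        "experiment",
    }
    _check_keys(doc, top_keys, "top level")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version must be {SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}"
        )
    try:
        kin = doc["kinetics"]
        _check_keys(kin, {"recB", "recD"}, "kinetics")
        recB = _motor(kin["recB"], "kinetics.recB")
        recD = _motor(kin["recD"], "kinetics.recD")

        swing_block = doc["swing"]
        _check_keys(
            swing_block,
            {"tau_chi_ms", "tau_stop_ms", "cv", "chi_offset_nt"},
            "swing",
        )
        swing = SwingModel(**swing_block)

        enz_block = doc["enzyme"]
        _check_keys(enz_block, {"p_chi_recognition", "k_sens_uM"}, "enzyme")

        entries = []
        for i, row in enumerate(doc["calibration"]):
            _check_keys(
                row, {"inhibitor_uM", "ratio", "advance_nt"}, f"calibration[{i}]"
            )
            entries.append(CalibrationEntry(**row))
        table = CalibrationTable(entries)

        enzyme = EnzymeParams(
            recB=recB,
            recD=recD,
            swing=swing,
            calibration=table,
            **enz_block,
        )

        gel_block = doc["gel"]
        _check_keys(
            gel_block,
            {"a_mm", "b_mm", "sigma_mm", "min_length_nt", "max_length_nt"},
            "gel",
        )
        gel = GelParams(**gel_block)

        sub_block = doc["substrates"]
        _check_keys(sub_block, {"lengths_nt", "chi_cut_from_label_nt"}, "substrates")

        obs = []
        for i, row in enumerate(doc["ic50_observations"]):
            _check_keys(row, {"atp_uM", "ic50_uM"}, f"ic50_observations[{i}]")
            obs.append(Ic50Observation(**row))

        na = doc["nuclease_assay"]
        _check_keys(
            na,
            {"atp_uM", "ic50_uM", "concentrations_uM", "replicates", "noise_cv"},
            "nuclease_assay",
        )
        assay = NucleaseAssaySettings(
            atp_uM=float(na["atp_uM"]),
            ic50_uM=float(na["ic50_uM"]),
            concentrations_uM=tuple(float(c) for c in na["concentrations_uM"]),
            replicates=int(na["replicates"]),
            noise_cv=float(na["noise_cv"]),
        )

        exp = doc["experiment"]
        _check_keys(
            exp, {"concentrations_uM", "n_molecules", "noise", "seed"}, "experiment"
        )
        noise_block = exp.get("noise", {})
        _check_keys(noise_block, {"band_jitter_mm", "activity_cv"}, "experiment.noise")
        noise = NoiseModel(**noise_block)

        return RunConfig(
            enzyme=enzyme,
            gel=gel,
            marker_lengths_nt=tuple(float(m) for m in doc["markers_nt"]),
            substrate_lengths_nt=tuple(int(L) for L in sub_block["lengths_nt"]),
            chi_cut_from_label_nt=int(sub_block["chi_cut_from_label_nt"]),
            ic50_observations=tuple(obs),
            nuclease_assay=assay,
            concentrations_uM=tuple(float(c) for c in exp["concentrations_uM"]),
            n_molecules=int(exp["n_molecules"]),
            noise=noise,
            seed=int(exp.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required configuration key: {exc}") from exc
    except (TypeError, InvalidParameterError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: Optional[Union[str, Path]] = None) -> RunConfig:
    """Load a YAML configuration; with no path, the packaged defaults."""
    if path is None:
        text = (
            resources.files("chirace") / "data" / "defaults.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    return parse_config(doc)


def default_config() -> RunConfig:
    return load_config(None)


def default_enzyme() -> EnzymeParams:
    return default_config().enzyme


def default_gel() -> GelParams:
    return default_config().gel


def default_markers() -> List[Marker]:
    return default_config().markers()
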
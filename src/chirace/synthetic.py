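"""Generators of complete in-silico experiments.

Two assays are emulated, with the statistical structure the inference stage
assumes:

* the three-substrate cutting assay across an inhibitor titration, read out
  as gel lanes with a single-strand marker ladder;
* the radiolabeled-DNA solubilization dose-response at fixed ATP.

All randomness flows from a single seed through per-lane spawned streams,
so a fixed seed reproduces the experiment exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .defaults import NoiseModel, RunConfig, default_config
from .gel import GelLane, GelParams, Marker, render_lane
from .kinetics import relative_activity
from .params import (
    EnzymeParams,
    InvalidParameterError,
    MotorKinetics,
    ReactionConditions,
    SubstrateSpec,
)
from .race import simulate_population

#: Published design: three substrate lengths, Chi cut 970 nt from the label.
DEFAULT_SUBSTRATE_LENGTHS = (4350, 2270, 1340)
DEFAULT_CHI_CUT_FROM_LABEL = 970


def make_default_substrates(
    lengths_nt: Sequence[int] = DEFAULT_SUBSTRATE_LENGTHS,
    chi_cut_from_label_nt: int = DEFAULT_CHI_CUT_FROM_LABEL,
) -> List[SubstrateSpec]:
    """The three packaged substrate lengths, each as a (chi+, chi0) pair.

    Entry is from the right, the orientation in which Chi is active, with
    the 5' label on the distal (left) end.
    """
    subs: List[SubstrateSpec] = []
    for L in lengths_nt:
        subs.append(
            SubstrateSpec(
                name=f"{L}_chi+",
                length_nt=int(L),
                entry_end="right",
                chi_cut_from_label=chi_cut_from_label_nt,
            )
        )
        subs.append(
            SubstrateSpec(name=f"{L}_chi0", length_nt=int(L), entry_end="right")
        )
    return subs


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of one cutting experiment: which substrates, which inhibitor
    concentrations, how many molecules per lane, and the noise model."""

    substrates: tuple
    concentrations_uM: tuple
    n_molecules: int = 2000
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise InvalidParameterError("n_molecules must be >= 1")
        if not self.substrates or not self.concentrations_uM:
            raise InvalidParameterError("empty experiment design")

    @classmethod
    def from_run_config(cls, cfg: RunConfig, seed: Optional[int] = None) -> "ExperimentConfig":
        return cls(
            substrates=tuple(
                make_default_substrates(
                    cfg.substrate_lengths_nt, cfg.chi_cut_from_label_nt
                )
            ),
            concentrations_uM=cfg.concentrations_uM,
            n_molecules=cfg.n_molecules,
            noise=cfg.noise,
            seed=cfg.seed if seed is None else seed,
        )


def generate_cutting_experiment(
    cfg: ExperimentConfig,
    enzyme: EnzymeParams,
    gel: GelParams,
    markers: Sequence[Marker],
    mode: str = "table",
) -> List[GelLane]:
    """One rendered gel lane per (substrate × concentration).

    With the default substrates (three lengths × two Chi statuses) and six
    concentrations this is the full 36-lane design.  Concentrations missing
    from the calibration table raise a configuration error up front.
    """
    if mode == "table":
        if enzyme.calibration is None:
            raise InvalidParameterError("table mode requires a calibration table")
        missing = [
            c for c in cfg.concentrations_uM if c not in enzyme.calibration
        ]
        if missing:
            raise InvalidParameterError(
                f"concentration(s) {missing} μM missing from the calibration table"
            )
    root = np.random.SeedSequence(cfg.seed)
    design = [(sub, conc) for sub in cfg.substrates for conc in cfg.concentrations_uM]
    lane_seeds = root.spawn(len(design))  # one stream per lane, in design order
    lanes: List[GelLane] = []
    for (sub, conc), lane_ss in zip(design, lane_seeds):
        sim_rng, jitter_rng = (np.random.default_rng(s) for s in lane_ss.spawn(2))
        cond = ReactionConditions(inhibitor_uM=float(conc), mode=mode)
        frags = simulate_population(cfg.n_molecules, sub, enzyme, cond, sim_rng)
        lanes.append(
            render_lane(
                frags,
                gel,
                markers,
                band_jitter_mm=cfg.noise.band_jitter_mm,
                rng=jitter_rng,
            )
        )
    return lanes


def experiment_truth(cfg: ExperimentConfig, enzyme: EnzymeParams) -> dict:
    """Generating parameters of an experiment, for recovery tests."""
    truth = {
        "seed": cfg.seed,
        "n_molecules": cfg.n_molecules,
        "noise": {
            "band_jitter_mm": cfg.noise.band_jitter_mm,
            "activity_cv": cfg.noise.activity_cv,
        },
        "k_sens_uM": enzyme.k_sens_uM,
        "p_chi_recognition": enzyme.p_chi_recognition,
        "substrates": [
            {
                "name": s.name,
                "length_nt": s.length_nt,
                "chi_cut_from_label": s.chi_cut_from_label,
            }
            for s in cfg.substrates
        ],
    }
    if enzyme.calibration is not None:
        truth["calibration"] = [
            {
                "inhibitor_uM": e.inhibitor_uM,
                "ratio": e.ratio,
                "advance_nt": e.advance_nt,
            }
            for e in enzyme.calibration
        ]
    return truth


def nuclease_assay_kinetics(
    ic50_uM: float, atp_uM: float, km_atp: float, v_max: float = 1.0
) -> MotorKinetics:
    """Motor kinetics whose Cheng–Prusoff IC50 at ``atp_uM`` equals the
    requested value: Ki = IC50 / (1 + [ATP]/Km)."""
    return MotorKinetics(
        v_max=v_max, km_atp=km_atp, ki_inh=ic50_uM / (1.0 + atp_uM / km_atp)
    )


def generate_nuclease_assay(
    kin: MotorKinetics,
    atp_uM: float,
    concentrations_uM: Sequence[float],
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    recD: Optional[MotorKinetics] = None,
) -> pd.DataFrame:
    """Synthetic solubilization dose-response table.

    Activity per replicate is the rate-law relative activity times
    ``1 + N(0, noise_cv)``, clamped at zero.  Columns: ``inhibitor_uM``,
    ``atp_uM``, ``activity_fraction``, ``replicate``.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    enz = EnzymeParams(recB=kin, recD=recD if recD is not None else kin)
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations_uM:
        cond = ReactionConditions(
            atp_uM=atp_uM, inhibitor_uM=float(conc), mode="kinetic"
        )
        truth = relative_activity(enz, cond)
        for rep in range(1, replicates + 1):
            noisy = truth * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else truth
            rows.append(
                {
                    "inhibitor_uM": float(conc),
                    "atp_uM": float(atp_uM),
                    "activity_fraction": max(0.0, noisy),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def generate_default_nuclease_assay(
    seed: int = 0, cfg: Optional[RunConfig] = None
) -> pd.DataFrame:
    """Dose-response table from the packaged standard-condition settings."""
    cfg = cfg if cfg is not None else default_config()
    assay = cfg.nuclease_assay
    kin = nuclease_assay_kinetics(
        ic50_uM=assay.ic50_uM,
        atp_uM=assay.atp_uM,
        km_atp=cfg.enzyme.recB.km_atp,
    )
    return generate_nuclease_assay(
        kin,
        atp_uM=assay.atp_uM,
        concentrations_uM=assay.concentrations_uM,
        replicates=assay.replicates,
        noise_cv=assay.noise_cv,
        seed=seed,
    )
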
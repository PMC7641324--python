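#!/usr/bin/env python
"""Step 2 — generate the in-silico experiments.

Produces the full cutting-assay design (three substrate lengths × with/
without Chi × six inhibitor concentrations → 36 gel lanes) and the
solubilization dose-response table, both seeded, under results/experiment/.

The generated lanes reproduce the qualitative behavior of the wet assay:
a sharp ~970-nt Chi band without inhibitor, its replacement by a longer,
smeared end-stop band at high inhibitor on the mid-length substrate, and a
full-length-only lane for the Chi-less substrate without drug.
"""

import json
import sys
from pathlib import Path

from chirace import io as cio
from chirace.defaults import default_config
from chirace.inference import estimate_band_lengths
from chirace.synthetic import (
    ExperimentConfig,
    experiment_truth,
    generate_cutting_experiment,
    generate_default_nuclease_assay,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "experiment"


def main(seed: int = 0) -> None:
    cfg = default_config()
    exp = ExperimentConfig.from_run_config(cfg, seed=seed)
    lanes = generate_cutting_experiment(exp, cfg.enzyme, cfg.gel, cfg.markers())
    for lane in lanes:
        cio.write_lane(lane, OUT / "lanes")
    (OUT / "markers.json").write_text(
        json.dumps([[L, d] for L, d in cfg.markers()], indent=1)
    )
    (OUT / "truth.json").write_text(
        json.dumps(experiment_truth(exp, cfg.enzyme), indent=1)
    )
    dose = generate_default_nuclease_assay(seed=seed, cfg=cfg)
    cio.write_dose_table(dose, OUT / "doseresponse.tsv")
    cio.write_manifest(OUT, seed, cio.config_hash("packaged-defaults"))
    print(f"wrote {len(lanes)} lanes + doseresponse.tsv under {OUT}")

    # narrate the race switch on the 2270-nt Chi-bearing substrate
    print("\n2270-nt chi+ substrate, sub-full-length bands per lane:")
    for lane in lanes:
        if lane.metadata["substrate"] != "2270_chi+":
            continue
        bands = [
            f"{b.length_nt:.0f} nt"
            for b in estimate_band_lengths(lane)
            if not b.is_full_length and b.length_nt is not None
        ]
        conc = lane.metadata["inhibitor_uM"]
        print(f"  [NSAC1003] = {conc:3g} uM: {', '.join(bands) or 'none'}")
    print(
        "The ~970-nt Chi band persists through 50 uM and is replaced by the "
        "longer end-stop product at 100-400 uM, as in the wet experiment."
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
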
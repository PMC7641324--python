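#!/usr/bin/env python
"""Step 4 — figures (optional, cosmetic).

Renders a lane gallery for the 2270-nt Chi-bearing substrate across the
titration, the product-length vs substrate-length fits, and the
dose-response curve, as PNGs under results/figures/.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from chirace import io as cio

ROOT = Path(__file__).resolve().parents[1] / "results"
EXP = ROOT / "experiment"
FIG = ROOT / "figures"


def lane_gallery() -> None:
    lanes = [
        l
        for l in cio.read_lanes_dir(EXP / "lanes")
        if l.metadata["substrate"] == "2270_chi+"
    ]
    lanes.sort(key=lambda l: l.metadata["inhibitor_uM"])
    fig, axes = plt.subplots(len(lanes), 1, figsize=(7, 9), sharex=True)
    for ax, lane in zip(axes, lanes):
        ax.plot(lane.distance_mm, lane.intensity, lw=0.8, color="k")
        ax.set_ylabel(f"{lane.metadata['inhibitor_uM']:g} uM", rotation=0,
                      ha="right", va="center", fontsize=8)
        ax.set_yticks([])
        for L, d in lane.markers:
            ax.axvline(d, color="0.85", lw=0.5, zorder=0)
    axes[-1].set_xlabel("migration distance (mm)")
    fig.suptitle("2270-nt chi+ lanes across the NSAC1003 titration")
    fig.tight_layout()
    fig.savefig(FIG / "lanes_2270_chiplus.png", dpi=150)


def product_vs_substrate() -> None:
    fits = json.loads((ROOT / "fits.json").read_text())["per_concentration"]
    fig, ax = plt.subplots(figsize=(5, 4))
    S = np.linspace(0, 4600, 10)
    for conc, res in sorted(fits.items(), key=lambda kv: float(kv[0])):
        ax.plot(S, res["slope"] * S + res["intercept_nt"], lw=1,
                label=f"{conc} uM (slope {res['slope']:.2f})")
        ax.scatter([1340, 2270, 4350],
                   [res["slope"] * x + res["intercept_nt"] for x in (1340, 2270, 4350)],
                   s=12)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("substrate length (nt)")
    ax.set_ylabel("labeled product length (nt)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(FIG / "product_vs_substrate.png", dpi=150)


def dose_response() -> None:
    df = cio.read_dose_table(EXP / "doseresponse.tsv")
    fit = json.loads((ROOT / "fits.json").read_text())["dose_response"]
    I = np.linspace(0, 80, 200)
    curve = fit["bottom"] + (fit["top"] - fit["bottom"]) / (
        1 + (I / fit["ic50_uM"]) ** fit["hill"]
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df.inhibitor_uM, df.activity_fraction, s=12, color="k",
               label="synthetic replicates")
    ax.plot(I, curve, color="tab:red",
            label=f"4PL fit, IC50 = {fit['ic50_uM']:.2f} uM")
    ax.set_xlabel("[NSAC1003] (uM)")
    ax.set_ylabel("relative nuclease activity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(FIG / "dose_response.png", dpi=150)


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    lane_gallery()
    product_vs_substrate()
    dose_response()
    print(f"wrote figures under {FIG}")


if __name__ == "__main__":
    main()
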
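"""Plain-text readers and writers: lane TSVs with JSON sidecars, fragment
and dose-response tables, and run manifests.  No binary formats."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .gel import GelLane, Marker
from .race import FragmentSet

PathLike = Union[str, Path]


def lane_basename(lane: GelLane) -> str:
    meta = lane.metadata
    conc = meta.get("inhibitor_uM", 0)
    conc_txt = f"{conc:g}".replace(".", "p")
    return f"{meta.get('substrate', 'lane')}_I{conc_txt}"


def write_lane(lane: GelLane, out_dir: PathLike) -> Path:
    """Write one lane as <name>.tsv (distance_mm, intensity) plus a JSON
    sidecar <name>.json with markers and metadata.  Returns the TSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = lane_basename(lane)
    tsv = out_dir / f"{name}.tsv"
    pd.DataFrame(
        {"distance_mm": lane.distance_mm, "intensity": lane.intensity}
    ).to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    sidecar = {
        "markers": [[L, d] for L, d in lane.markers],
        "metadata": lane.metadata,
    }
    (out_dir / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    return tsv


def read_lane(tsv_path: PathLike) -> GelLane:
    tsv_path = Path(tsv_path)
    side = json.loads(tsv_path.with_suffix(".json").read_text())
    df = pd.read_csv(tsv_path, sep="\t")
    return GelLane(
        distance_mm=df["distance_mm"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        markers=tuple((float(L), float(d)) for L, d in side["markers"]),
        metadata=side["metadata"],
    )


def read_lanes_dir(lanes_dir: PathLike) -> List[GelLane]:
    lanes_dir = Path(lanes_dir)
    return [read_lane(p) for p in sorted(lanes_dir.glob("*.tsv"))]


def write_fragments(fragsets: Iterable[FragmentSet], path: PathLike) -> Path:
    """Serialize fragment populations as a TSV with columns substrate,
    chi_status, inhibitor_uM, fragment_length_nt, count, trigger."""
    rows = []
    for fs in fragsets:
        for rec in fs.records:
            rows.append(
                {
                    "substrate": fs.substrate.name,
                    "chi_status": fs.substrate.chi_status,
                    "inhibitor_uM": fs.inhibitor_uM,
                    "fragment_length_nt": rec.length_nt,
                    "count": rec.count,
                    "trigger": rec.trigger,
                }
            )
        if fs.full_length_count:
            rows.append(
                {
                    "substrate": fs.substrate.name,
                    "chi_status": fs.substrate.chi_status,
                    "inhibitor_uM": fs.inhibitor_uM,
                    "fragment_length_nt": fs.substrate.length_nt,
                    "count": fs.full_length_count,
                    "trigger": "none",
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_dose_table(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_dose_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(path_or_text: Union[PathLike, str]) -> str:
    p = Path(path_or_text) if not str(path_or_text).count("\n") else None
    text = p.read_text() if p is not None and p.exists() else str(path_or_text)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(out_dir: PathLike, seed: int, cfg_hash: str, extra: dict | None = None) -> Path:
    """Record seed, config hash and versions so a run is reproducible."""
    manifest = {
        "seed": int(seed),
        "config_hash": cfg_hash,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }
    if extra:
        manifest.update(extra)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
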
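"""File schemas: BinTable CSV, lane-profile CSV, gel bundles with manifest
JSON, calibration reports, and config loading (JSON/YAML).

All data files are UTF-8 CSV with '.' decimals and a mandatory header;
fractions are written with six decimal places so reruns under a fixed seed
are byte-identical.  Every primary output gets a sidecar manifest recording
a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gel import LaneProfile

__all__ = [
    "write_bin_table",
    "read_bin_table",
    "write_lane_csv",
    "read_lane_csv",
    "write_gel_bundle",
    "read_gel_bundle",
    "config_hash",
    "write_manifest",
    "load_config",
]

BIN_TABLE_COLUMNS = [
    "condition", "tfs", "replicate", "time_s",
    "bin1", "bin2", "bin3", "bin4", "bin5", "bin6", "bin7",
]


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(path: Path, config: dict, extra: dict | None = None) -> None:
    doc = {"config_hash": config_hash(config), "config": config}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_bin_table(table: pd.DataFrame, path: Path) -> None:
    missing = [c for c in BIN_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"bin table missing columns: {missing}")
    out = table[BIN_TABLE_COLUMNS].copy()
    out["time_s"] = out["time_s"].map(
        lambda t: int(t) if float(t).is_integer() else float(t)
    )
    for c in BIN_TABLE_COLUMNS[4:]:
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_bin_table(path: Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in BIN_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"malformed bin table {path}: missing column(s) {missing}"
        )
    fracs = table[BIN_TABLE_COLUMNS[4:]].to_numpy(dtype=float)
    bad = np.abs(fracs.sum(axis=1) - 1.0) > 1e-4
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} row(s) in {path} have fractions not summing to 1"
        )
    return table


def write_lane_csv(profile: LaneProfile, path: Path) -> None:
    pd.DataFrame(
        {"pixel": np.arange(profile.pixel_count), "intensity": profile.intensities}
    ).to_csv(path, index=False)


def read_lane_csv(path: Path) -> LaneProfile:
    df = pd.read_csv(path)
    for col in ("pixel", "intensity"):
        if col not in df.columns:
            raise ValueError(f"lane CSV {path} missing column {col!r}")
    return LaneProfile(df["intensity"].to_numpy(dtype=float), label=Path(path).stem)


def write_gel_bundle(
    out_dir: Path,
    sample_lanes: list[tuple[dict, LaneProfile]],
    marker_profile: LaneProfile,
    marker_lengths: list[float],
    config: dict,
) -> Path:
    """Write a gel bundle: one CSV per lane plus a manifest.

    ``sample_lanes`` pairs lane metadata (condition, tfs, replicate,
    time_s) with profiles.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lanes = []
    write_lane_csv(marker_profile, out_dir / "lane_marker.csv")
    for i, (meta, profile) in enumerate(sample_lanes):
        fname = f"lane_{i:03d}.csv"
        write_lane_csv(profile, out_dir / fname)
        lanes.append({**meta, "file": fname})
    manifest = {
        "marker_file": "lane_marker.csv",
        "marker_lengths": list(marker_lengths),
        "lanes": lanes,
        "config_hash": config_hash(config),
        "config": config,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return mpath


def read_gel_bundle(bundle_dir: Path) -> dict:
    """Load a gel bundle directory into profiles + metadata."""
    bundle_dir = Path(bundle_dir)
    mpath = bundle_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {bundle_dir}")
    manifest = json.loads(mpath.read_text())
    if not manifest.get("lanes"):
        raise ValueError(f"gel bundle {bundle_dir} has no sample lanes")
    marker = read_lane_csv(bundle_dir / manifest["marker_file"])
    lanes = [
        (
            {k: v for k, v in entry.items() if k != "file"},
            read_lane_csv(bundle_dir / entry["file"]),
        )
        for entry in manifest["lanes"]
    ]
    return {
        "marker_profile": marker,
        "marker_lengths": manifest["marker_lengths"],
        "lanes": lanes,
        "manifest": manifest,
    }


def load_config(path: Path) -> dict:
    """Read a JSON or YAML configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
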
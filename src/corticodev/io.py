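"""Readers and writers for the package's CSV/JSON artifacts.

All artifacts are plain text: per-area and per-soma sheet snapshots,
synapse tables, connectome matrices and edge lists, pairwise structural
measures, empirical-format datasets (CSV plus a species sidecar JSON) and
run manifests with SHA-256 checksums. Write-then-read round-trips
reproduce the in-memory objects exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import EmpiricalDataset
from .connectome import AreaConnectome, PairMeasures, offdiag_mask
from .layouts import GrowthLayoutConfig
from .sheet import CorticalSheet


class ParseError(ValueError):
    """Malformed artifact file."""


# ----------------------------------------------------------------------
# layouts

def registry_to_json(configs: list[GrowthLayoutConfig], path: Path | str) -> None:
    payload = [dataclasses.asdict(c) for c in configs]
    Path(path).write_text(json.dumps(payload, indent=1))


def registry_from_json(path: Path | str) -> list[GrowthLayoutConfig]:
    payload = json.loads(Path(path).read_text())
    return [GrowthLayoutConfig(**entry) for entry in payload]


# ----------------------------------------------------------------------
# sheets

def sheet_to_area_frame(sheet: CorticalSheet) -> pd.DataFrame:
    a = sheet.area_side
    rows = []
    for area in sheet.areas:
        cx, cy = area.centroid(a)
        rows.append(
            dict(
                area_id=area.area_id,
                origin_id=area.origin_id,
                creation_event=area.creation_event,
                density=area.density,
                centroid_x=cx,
                centroid_y=cy,
                n_somata=area.n_active,
            )
        )
    return pd.DataFrame(rows)


def sheet_to_soma_frame(sheet: CorticalSheet) -> pd.DataFrame:
    frames = []
    neuron_id = 0
    for area in sheet.areas:
        p = area.soma_positions(sheet.area_side)
        frames.append(
            pd.DataFrame(
                {
                    "neuron_id": np.arange(neuron_id, neuron_id + len(p)),
                    "area_id": area.area_id,
                    "x": p[:, 0],
                    "y": p[:, 1],
                }
            )
        )
        neuron_id += len(p)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["neuron_id", "area_id", "x", "y"]
    )


# ----------------------------------------------------------------------
# synapses / connectomes / measures

def write_synapses(synapses: pd.DataFrame, path: Path | str) -> None:
    synapses.to_csv(path, index=False)


def read_synapses(path: Path | str) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = ["source_neuron_id", "target_neuron_id", "time_step"]
    _require_columns(frame, required, path)
    return frame[required].astype(np.int64)


def write_connectome(connectome: AreaConnectome, path: Path | str) -> None:
    pd.DataFrame(connectome.axon_counts).to_csv(path, index=False)


def read_connectome(path: Path | str, min_axons: int = 1) -> AreaConnectome:
    frame = pd.read_csv(path)
    counts = frame.to_numpy(dtype=np.int64)
    if counts.shape[0] != counts.shape[1]:
        raise ParseError(f"{path}: connectome matrix must be square, got {counts.shape}")
    return AreaConnectome(counts, min_axons)


def write_edge_list(connectome: AreaConnectome, path: Path | str) -> None:
    src, tgt = np.nonzero(offdiag_mask(connectome.n_areas))
    pd.DataFrame(
        {
            "source_area": src,
            "target_area": tgt,
            "axon_count": connectome.axon_counts[src, tgt],
            "exists": connectome.exists[src, tgt].astype(int),
        }
    ).to_csv(path, index=False)


def write_pair_measures(measures: PairMeasures, path: Path | str) -> None:
    src, tgt = np.nonzero(offdiag_mask(measures.n_areas))
    pd.DataFrame(
        {
            "source_area": src,
            "target_area": tgt,
            "density_diff": measures.density_difference[src, tgt],
            "abs_density_diff": measures.abs_density_difference[src, tgt],
            "distance": measures.distance[src, tgt],
        }
    ).to_csv(path, index=False, float_format="%.17g")


# ----------------------------------------------------------------------
# empirical-format datasets

def write_empirical(dataset: EmpiricalDataset, csv_path: Path | str) -> None:
    csv_path = Path(csv_path)
    dataset.frame.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({"species_label": dataset.species_label}))


def read_empirical(csv_path: Path | str, species_label: str | None = None) -> EmpiricalDataset:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    _require_columns(frame, list(EmpiricalDataset.REQUIRED), csv_path)
    if species_label is None:
        sidecar = csv_path.with_suffix(".json")
        if sidecar.exists():
            species_label = json.loads(sidecar.read_text()).get("species_label", "unknown")
        else:
            species_label = "unknown"
    return EmpiricalDataset(species_label=species_label, frame=frame)


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing} in header line 1")


# ----------------------------------------------------------------------
# run manifests

def sha256_of(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path | str, meta: dict, files: list[Path | str]) -> Path:
    out_dir = Path(out_dir)
    manifest = dict(meta)
    manifest["files"] = {
        str(Path(f).relative_to(out_dir)): sha256_of(f) for f in files
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def verify_manifest(out_dir: Path | str) -> dict:
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for rel, digest in manifest["files"].items():
        f = out_dir / rel
        if not f.exists():
            raise ParseError(f"manifest lists missing file {rel}")
        if sha256_of(f) != digest:
            raise ParseError(f"checksum mismatch for {rel}")
    return manifest
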
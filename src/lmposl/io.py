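"""Reading and writing the pipeline's on-disk dialects.

Images travel as single-channel 16-bit TIFF plus a YAML session manifest;
depth-dose curves and spectra as CSV; SOBP specs and fitted efficiency
models as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .efficiency import EfficiencyCurve
from .imaging import DetectorImage, Role
from .transport import DepthDose, EnergySpectrumAtDepth, SobpSpec


# --- image sessions --------------------------------------------------------

def save_session(directory: str | Path, frames: Sequence[DetectorImage],
                 manifest_name: str = "manifest.yaml") -> Path:
    """Write frames as TIFFs plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, frame in enumerate(frames):
        stem = f"{frame.detector_id or 'shared'}_{frame.role.value}_{i:03d}.tif"
        tifffile.imwrite(directory / stem, frame.pixels.astype(np.uint16))
        entries.append({
            "path": stem,
            "role": frame.role.value,
            "detector_id": frame.detector_id,
            "acquired_at": float(frame.acquired_at),
        })
    manifest = directory / manifest_name
    manifest.write_text(yaml.safe_dump({"frames": entries}, sort_keys=False))
    return manifest


def load_session(manifest_path: str | Path) -> list[DetectorImage]:
    """Load a session written by :func:`save_session` (or hand-authored)."""
    manifest_path = Path(manifest_path)
    spec = yaml.safe_load(manifest_path.read_text())
    frames = []
    for entry in spec["frames"]:
        pixels = tifffile.imread(manifest_path.parent / entry["path"])
        frames.append(DetectorImage(
            pixels=pixels,
            acquired_at=float(entry.get("acquired_at", 0.0)),
            role=Role(entry["role"]),
            detector_id=str(entry.get("detector_id", "")),
        ))
    return frames


# --- tabular transport output ----------------------------------------------

def write_depth_dose(path: str | Path, dd: DepthDose) -> None:
    dd.to_frame().to_csv(path, index=False)


def read_depth_dose(path: str | Path, normalization: str = "raw") -> DepthDose:
    df = pd.read_csv(path)
    return DepthDose(df["depth_mm"].to_numpy(), df["dose_rel"].to_numpy(),
                     normalization=normalization)


def write_spectra(path: str | Path, spectra: Sequence[EnergySpectrumAtDepth]) -> None:
    """Long-format CSV: depth_mm, bin_lo_MeV, bin_hi_MeV, count (occupied bins)."""
    rows = []
    for sp in spectra:
        occupied = np.nonzero(sp.counts)[0]
        for j in occupied:
            rows.append((sp.depth_mm, sp.bin_edges[j], sp.bin_edges[j + 1],
                         sp.counts[j]))
    pd.DataFrame(rows, columns=["depth_mm", "bin_lo_MeV", "bin_hi_MeV",
                                "count"]).to_csv(path, index=False)


def read_spectra(path: str | Path) -> list[EnergySpectrumAtDepth]:
    df = pd.read_csv(path)
    spectra = []
    for depth, group in df.groupby("depth_mm", sort=True):
        edges = np.linspace(0.0, EnergySpectrumAtDepth.E_MAX,
                            EnergySpectrumAtDepth.N_BINS + 1)
        counts = np.zeros(EnergySpectrumAtDepth.N_BINS)
        idx = np.searchsorted(edges, group["bin_lo_MeV"].to_numpy(), side="left")
        counts[idx] = group["count"].to_numpy()
        med, iqr = _summary_or_nan(edges, counts)
        spectra.append(EnergySpectrumAtDepth(depth_mm=float(depth), bin_edges=edges,
                                             counts=counts, median=med, iqr=iqr))
    return spectra


def _summary_or_nan(edges: np.ndarray, counts: np.ndarray) -> tuple[float, float]:
    from .transport import _histogram_quantile

    if counts.sum() <= 0:
        return float("nan"), float("nan")
    q25, med, q75 = _histogram_quantile(edges, counts, [0.25, 0.5, 0.75])
    return float(med), float(q75 - q25)


# --- model / spec JSON ------------------------------------------------------

def write_curve(path: str | Path, curve: EfficiencyCurve) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(curve), indent=2))


def read_curve(path: str | Path) -> EfficiencyCurve:
    return EfficiencyCurve(**json.loads(Path(path).read_text()))


def write_sobp_spec(path: str | Path, spec: SobpSpec) -> None:
    Path(path).write_text(json.dumps({
        "components": [{"pmma_thickness_mm": t, "weight": w}
                       for t, w in spec.components],
        "plateau": list(spec.plateau),
    }, indent=2))


def read_sobp_spec(path: str | Path) -> SobpSpec:
    data = json.loads(Path(path).read_text())
    return SobpSpec(
        components=[(c["pmma_thickness_mm"], c["weight"])
                    for c in data["components"]],
        plateau=tuple(data["plateau"]),
    )
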
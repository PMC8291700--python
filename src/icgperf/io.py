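"""File formats: TIFF scene stacks with JSON sidecars, curve/flow CSVs,
study manifests, and scoring tables.

A simulated or recorded scene is stored as a multi-page grayscale TIFF plus
a JSON sidecar holding the frame times, the ROI masks as axis-aligned
rectangles ``[row0, row1, col0, col1]`` (half-open), and — for simulated
scenes — the generative ground truth.  Curves are two-column CSVs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .curves import IntensityCurve
from .simulate import FlowTrace, Group, KineticParams, SceneStack, SimulatedStudy, Timepoint

CURVE_COLUMNS = ("time_s", "intensity_au")
FLOW_COLUMNS = ("time_s", "value")
MANIFEST_COLUMNS = (
    "animal_id", "group", "roi", "timepoint", "curve_file", "flow_file",
)


# --------------------------------------------------------------------------
# Curves and flow traces
# --------------------------------------------------------------------------

def write_curve_csv(curve: IntensityCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {CURVE_COLUMNS[0]: curve.time, CURVE_COLUMNS[1]: curve.intensity}
    ).to_csv(path, index=False)
    return path


def read_curve_csv(path: str | Path, roi: str | None = None) -> IntensityCurve:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: curve CSV needs two columns, got {cols}")
    return IntensityCurve(
        time=df[cols[0]].to_numpy(float),
        intensity=df[cols[1]].to_numpy(float),
        roi=roi,
    )


def write_flow_csv(trace: FlowTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {FLOW_COLUMNS[0]: trace.time, FLOW_COLUMNS[1]: trace.flow}
    ).to_csv(path, index=False)
    return path


def read_flow_csv(path: str | Path, group: Group, phase: Timepoint) -> FlowTrace:
    df = pd.read_csv(path)
    cols = list(df.columns)
    return FlowTrace(
        time=df[cols[0]].to_numpy(float),
        flow=df[cols[1]].to_numpy(float),
        group=Group(group),
        phase=Timepoint(phase),
    )


# --------------------------------------------------------------------------
# Scenes
# --------------------------------------------------------------------------

def _mask_to_rect(mask: np.ndarray) -> list[int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    rect = [int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1]
    full = np.zeros_like(mask)
    full[rect[0]:rect[1], rect[2]:rect[3]] = True
    if not np.array_equal(full, mask):
        raise ValueError("only rectangular ROI masks can be serialized")
    return rect


def write_scene(stack: SceneStack, tiff_path: str | Path) -> tuple[Path, Path]:
    """Write a scene as multi-page TIFF + ``<stem>.json`` sidecar."""
    tiff_path = Path(tiff_path)
    sidecar = tiff_path.with_suffix(".json")
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    meta = {
        "frame_times_s": stack.frame_times.tolist(),
        "roi_rects": {
            roi: _mask_to_rect(mask) for roi, mask in stack.roi_masks.items()
        },
        "ground_truth": {
            roi: dataclasses.asdict(p) for roi, p in stack.ground_truth.items()
        },
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return tiff_path, sidecar


def read_scene(tiff_path: str | Path, sidecar: str | Path | None = None) -> SceneStack:
    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar) if sidecar else tiff_path.with_suffix(".json")
    frames = tifffile.imread(tiff_path)
    meta = json.loads(sidecar.read_text())
    shape = frames.shape[1:]
    masks = {}
    for roi, (r0, r1, c0, c1) in meta["roi_rects"].items():
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        masks[roi] = mask
    truth = {
        roi: KineticParams(**p) for roi, p in meta.get("ground_truth", {}).items()
    }
    return SceneStack(
        frames=frames,
        frame_times=np.asarray(meta["frame_times_s"], dtype=float),
        roi_masks=masks,
        ground_truth=truth,
    )


# --------------------------------------------------------------------------
# Whole studies
# --------------------------------------------------------------------------

def write_study(study: SimulatedStudy, out_dir: str | Path) -> Path:
    """Write a simulated study: per-measurement curve CSVs, per-(animal,
    timepoint) flow CSVs, a manifest, macroscopic-score inputs, and
    histology descriptors.  Returns the manifest path."""
    out = Path(out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    (out / "flows").mkdir(exist_ok=True)

    flow_files: dict[tuple[str, str], str] = {}
    for (animal, phase), trace in study.flow_traces.items():
        rel = f"flows/{animal}_{phase.value.replace('+', 'p')}.csv"
        write_flow_csv(trace, out / rel)
        flow_files[(animal, phase.value)] = rel

    manifest_rows, macro_rows = [], []
    for m in study:
        tp = m.timepoint.value
        rel = f"curves/{m.animal_id}_{m.roi.value}_{tp.replace('+', 'p')}.csv"
        write_curve_csv(m.curve, out / rel)
        manifest_rows.append(
            {
                "animal_id": m.animal_id,
                "group": m.group.value,
                "roi": m.roi.value,
                "timepoint": tp,
                "curve_file": rel,
                "flow_file": flow_files[(m.animal_id, tp)],
            }
        )
        macro_rows.append(
            {
                "animal_id": m.animal_id,
                "roi": m.roi.value,
                "timepoint": tp,
                "color": m.macro.color,
                "peristalsis": m.macro.peristalsis,
                "edema": m.macro.edema,
                "hemorrhage": m.macro.mesenteric_hemorrhage,
            }
        )

    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    pd.DataFrame(macro_rows).to_csv(out / "macro_inputs.csv", index=False)

    histo_rows = []
    for (animal, roi), desc in study.histology.items():
        row = {"specimen_id": f"{animal}_{roi.value}", **dataclasses.asdict(desc)}
        histo_rows.append(row)
    pd.DataFrame(histo_rows).to_csv(out / "histology_inputs.csv", index=False)
    return manifest


def read_study_curves(manifest_path: str | Path):
    """Yield ``(manifest row, IntensityCurve)`` pairs for a study on disk."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    for _, row in df.iterrows():
        yield row, read_curve_csv(base / row["curve_file"], roi=row["roi"])


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{manifest_path}: manifest lacks column(s) {missing}")
    return df
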
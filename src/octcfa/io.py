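"""Reading and writing pullback masks, sidecar metadata and cohort tables.

Masks travel as multi-page TIFF (one page per frame, uint8 labels 0-9) or
as a NIfTI label volume, chosen by file extension, with a sidecar JSON
carrying the physical metadata the masks cannot: pixel spacing (um),
A-line count, per-frame artefact A-line indices, and lesion spans as
0-based half-open intervals. Tables are plain CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .frame import SegmentationFrame

CALLS_COLUMNS = [
    "scope",
    "patient_id",
    "unit_id",
    "evaluable",
    "ai_tcfa",
    "corelab_tcfa",
]
SURVIVAL_COLUMNS = [
    "patient_id",
    "time_days",
    "event",
    "event_type",
    "exposure_target_lesion",
    "exposure_complete_segment",
]
METRICS_COLUMNS = [
    "pullback_id",
    "frame_index",
    "lipid_arc_deg",
    "min_cap_um",
    "analyzable",
    "excluded",
]


class SchemaError(ValueError):
    """A table does not match its documented column dictionary."""


def sidecar_path(mask_path) -> Path:
    p = Path(mask_path)
    name = p.name
    for suffix in (".nii.gz", ".nii", ".tif", ".tiff"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def write_pullback(
    frames: List[SegmentationFrame],
    mask_path,
    lesion_spans: Dict[str, Tuple[int, int]] | None = None,
) -> None:
    """Write a pullback's masks plus sidecar JSON metadata."""
    mask_path = Path(mask_path)
    stack = np.stack([f.labels for f in frames]).astype(np.uint8)
    if mask_path.name.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(stack, affine=np.eye(4)), str(mask_path))
    else:
        tifffile.imwrite(str(mask_path), stack)
    meta = {
        "pixel_spacing_um": frames[0].pixel_spacing_um,
        "n_alines": frames[0].n_alines,
        "artefact_alines": {
            str(f.frame_index): sorted(f.artefact_alines)
            for f in frames
            if f.artefact_alines
        },
        "lesion_spans": {
            k: [int(v[0]), int(v[1])] for k, v in (lesion_spans or {}).items()
        },
        "n_frames": len(frames),
    }
    sidecar_path(mask_path).write_text(json.dumps(meta, indent=1))


def read_pullback(mask_path):
    """Read masks + sidecar back into frames and the lesion-span dict."""
    mask_path = Path(mask_path)
    if mask_path.name.endswith((".nii", ".nii.gz")):
        stack = np.asarray(nib.load(str(mask_path)).dataobj).astype(np.uint8)
    else:
        stack = tifffile.imread(str(mask_path))
        if stack.ndim == 2:
            stack = stack[None]
    meta = json.loads(sidecar_path(mask_path).read_text())
    artefacts = {int(k): frozenset(v) for k, v in meta["artefact_alines"].items()}
    frames = [
        SegmentationFrame(
            labels=stack[i],
            pixel_spacing_um=meta["pixel_spacing_um"],
            n_alines=meta["n_alines"],
            artefact_alines=artefacts.get(i, frozenset()),
            frame_index=i,
        )
        for i in range(stack.shape[0])
    ]
    spans = {k: (v[0], v[1]) for k, v in meta["lesion_spans"].items()}
    return frames, spans


def validate_table(df: pd.DataFrame, required: List[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError(f"{name} table is empty")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df, CALLS_COLUMNS[:5], "calls")
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_table(df, SURVIVAL_COLUMNS[:4], "survival")
    return df
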
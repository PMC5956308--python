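"""Readers and writers for the pipeline's on-disk formats.

Frames travel as multi-page TIFF stacks or directories of numbered
PNG/TIFF images; stage offsets as CSV (frame_index, dx_px, dy_px); traced
capillary paths and ground truth as JSON; cohort tables and reports as
CSV/JSON; configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import CapillaryPath
from .errors import InvalidInputError
from .mosaic import VideoSequence


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def write_frames(path, frames, fmt: str = "tiff"):
    """Write frames as one multi-page TIFF (fmt='tiff') or numbered PNGs.

    Float images are stored as float32 TIFF; PNG output is rescaled to
    uint8 over [0, 255] with clipping.
    """
    path = Path(path)
    stack = np.asarray(frames, dtype=np.float32)
    if fmt == "tiff":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack)
        return path
    if fmt == "png":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            u8 = np.clip(frame, 0, 255).astype(np.uint8)
            iio.imwrite(path / f"frame_{i:05d}.png", u8)
        return path
    raise InvalidInputError(f"unknown frame format {fmt!r}")


def read_frames(path) -> list:
    """Read a multi-page TIFF stack or a directory of numbered images."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise InvalidInputError(f"no image files in {path}")
        return [np.asarray(iio.imread(p), dtype=float) for p in files]
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        return [np.asarray(stack, dtype=float)]
    return [np.asarray(f, dtype=float) for f in stack]


def write_offsets_csv(path, offsets):
    offsets = np.asarray(offsets, dtype=float)
    df = pd.DataFrame({
        "frame_index": np.arange(len(offsets)),
        "dx_px": offsets[:, 0],
        "dy_px": offsets[:, 1],
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_offsets_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    for col in ("frame_index", "dx_px", "dy_px"):
        if col not in df.columns:
            raise InvalidInputError(f"offsets CSV missing column {col!r}")
    df = df.sort_values("frame_index")
    return df[["dx_px", "dy_px"]].to_numpy(dtype=float)


def read_video(frames_path, frame_rate_hz, pixel_scale_um,
               offsets_path=None) -> VideoSequence:
    frames = read_frames(frames_path)
    offsets = read_offsets_csv(offsets_path) if offsets_path else None
    return VideoSequence(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        pixel_scale_um=pixel_scale_um,
        nominal_offsets=offsets,
    )


# ---------------------------------------------------------------------------
# capillary paths
# ---------------------------------------------------------------------------

def paths_to_json(paths, file=None) -> str:
    payload = []
    for p in paths:
        payload.append({
            "apex_xy": [float(v) for v in p.apex_xy],
            "points": np.asarray(p.points, dtype=float).tolist(),
            "orientations": np.asarray(p.orientations, dtype=float).tolist(),
            "widths": [None if not np.isfinite(w) else float(w) for w in p.widths],
            "width_valid": np.asarray(p.width_valid, dtype=bool).tolist(),
            "apex_index": int(p.apex_index),
            "limb_arc_lengths_um": [float(v) for v in p.limb_arc_lengths_um],
            "detection_score": float(p.detection_score),
            "pixel_scale_um": float(p.pixel_scale_um),
        })
    text = json.dumps(payload, indent=2)
    if file is not None:
        Path(file).parent.mkdir(parents=True, exist_ok=True)
        Path(file).write_text(text)
    return text


def paths_from_json(source) -> list:
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        payload = json.loads(Path(source).read_text())
    else:
        payload = json.loads(source)
    out = []
    for rec in payload:
        widths = np.array(
            [np.nan if w is None else w for w in rec["widths"]], dtype=float
        )
        out.append(CapillaryPath(
            apex_xy=np.asarray(rec["apex_xy"], dtype=float),
            points=np.asarray(rec["points"], dtype=float),
            orientations=np.asarray(rec["orientations"], dtype=float),
            widths=widths,
            width_valid=np.asarray(rec["width_valid"], dtype=bool),
            apex_index=int(rec["apex_index"]),
            limb_arc_lengths_um=tuple(rec["limb_arc_lengths_um"]),
            detection_score=float(rec["detection_score"]),
            pixel_scale_um=float(rec["pixel_scale_um"]),
        ))
    return out


# ---------------------------------------------------------------------------
# tables, reports, config
# ---------------------------------------------------------------------------

def write_cohort_csv(path, table):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)


def read_cohort_csv(path):
    from .cohortstats import CohortTable
    return CohortTable(pd.read_csv(path))


def write_report(outdir, report):
    """Report JSON + rendered summary-table CSV + ROC curve points CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    report.to_dataframe().to_csv(outdir / "summary_table.csv", index=False)
    rows = []
    for key in ("structure", "structure_flow"):
        fpr, tpr = report.combined[key]["roc_curve"]
        for f, t in zip(fpr, tpr):
            rows.append({"model": key, "fpr": f, "tpr": t})
    pd.DataFrame(rows).to_csv(outdir / "roc_curves.csv", index=False)
    return outdir


def load_config_file(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def dump_config(config: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=True))
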
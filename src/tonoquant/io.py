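"""File formats: multi-page TIFF movies, ROI JSON/CSV, ground-truth tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .prep import CellROI, Movie


def save_movie(path: str | Path, movie: Movie) -> None:
    """Write a movie as multi-page 16-bit grayscale TIFF.

    Float intensities are rounded and clipped to the 16-bit range; frame
    interval and pixel size are embedded in the TIFF's JSON metadata.
    """
    frames = movie.frames
    if frames.dtype != np.uint16:
        frames = np.clip(np.round(np.asarray(frames, dtype=float)), 0, 65535).astype(
            np.uint16
        )
    tifffile.imwrite(
        str(path),
        frames,
        photometric="minisblack",
        metadata={
            "frame_interval_s": movie.frame_interval_s,
            "pixel_size_um": movie.pixel_size_um,
        },
    )


def load_movie(
    path: str | Path,
    frame_interval_s: float | None = None,
    pixel_size_um: float | None = None,
) -> Movie:
    """Read a multi-page TIFF; explicit calibration overrides embedded metadata."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = tif.shaped_metadata[0]
        elif tif.imagej_metadata:
            meta = tif.imagej_metadata
    if frames.ndim == 2:
        frames = frames[None]
    return Movie(
        frames=frames,
        frame_interval_s=float(
            frame_interval_s
            if frame_interval_s is not None
            else meta.get("frame_interval_s", 2.0)
        ),
        pixel_size_um=float(
            pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um", 0.11)
        ),
    )


def save_rois(path: str | Path, rois: list[CellROI]) -> None:
    """ROI list as JSON: [{cell_id, x0, y0, width, height, condition_label}, ...]."""
    payload = [
        {
            "cell_id": r.cell_id,
            "x0": r.x0,
            "y0": r.y0,
            "width": r.width,
            "height": r.height,
            "condition_label": r.condition_label,
            "root_surface": r.root_surface,
        }
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_rois(path: str | Path) -> list[CellROI]:
    """Read ROIs from JSON (list of objects) or CSV with the same columns."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        records = pd.read_csv(path).to_dict("records")
    else:
        records = json.loads(path.read_text())
    return [
        CellROI(
            cell_id=str(r["cell_id"]),
            x0=int(r["x0"]),
            y0=int(r["y0"]),
            width=int(r["width"]),
            height=int(r["height"]),
            condition_label=str(r.get("condition_label", "")),
            root_surface=bool(r.get("root_surface", True)),
        )
        for r in records
    ]


def save_ground_truth(out_dir: str | Path, cells, ground_truth: dict | None = None) -> None:
    """Per-cell geometry as CSV; per-frame transforms/displacements as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in cells:
        rows.append(
            {
                "cell_id": c.cell_id,
                "condition_label": c.condition_label,
                "x0": c.rect[0],
                "y0": c.rect[1],
                "width": c.rect[2],
                "height": c.rect[3],
                "length_um": c.length_um,
                "n_compartments": c.n_compartments,
                "max_radius_px": max(c.compartment_radii),
            }
        )
    pd.DataFrame(rows).to_csv(out / "cells_ground_truth.csv", index=False)
    if ground_truth is not None:
        payload = {
            "transforms": [list(t) for t in ground_truth["transforms"]],
            "mean_step_px": list(map(float, ground_truth["mean_step_px"])),
            "mean_cum_disp_px": list(map(float, ground_truth["mean_cum_disp_px"])),
            "clamp_events": int(ground_truth["clamp_events"]),
        }
        (out / "frame_ground_truth.json").write_text(json.dumps(payload, indent=1) + "\n")
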
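"""Vacuole morphometry: segmentation, VMI, and TTI.

Two complementary per-cell metrics of tonoplast complexity are computed
from a single confocal frame plus a rectangular cell ROI:

* **VMI** (vacuolar morphology index) — the size of the largest vacuolar
  compartment in the optical section, operationalized as the maximal Feret
  diameter times the maximal extent perpendicular to it (um^2), natural-log
  transformed for statistics (higher VMI = more consolidated vacuole).
* **TTI** (tonoplast topology index) — tonoplast membrane crossings per
  unit length of a diagonal cell transect (higher TTI = more convoluted /
  fragmented vacuome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .prep import CellROI


@dataclass
class SegmentationMask:
    """Label image of vacuole-lumen compartments within one cell ROI.

    Label 0 is non-lumen; labels 1..K are compartments (4-connected).
    ``border_labels`` flags compartments touching the ROI border (retained);
    ``degenerate`` is set when no membrane threshold could be found.
    """

    labels: np.ndarray
    pixel_size_um: float
    border_labels: frozenset[int] = frozenset()
    degenerate: bool = False

    @property
    def n_compartments(self) -> int:
        return int(self.labels.max())


@dataclass
class TTIResult:
    crossings: float
    transect_length_um: float
    tti_per_um: float
    degenerate: bool = False


@dataclass
class MorphologyRecord:
    """Per-cell morphometry row (CSV-serializable)."""

    cell_id: str
    condition_label: str
    length_um: float
    vmi_um2: float | None = None
    ln_vmi: float | None = None
    crossings: float | None = None
    transect_length_um: float | None = None
    tti_per_um: float | None = None
    n_compartments: int = 0
    root_surface: bool = True
    flags: str = ""


def segment_lumen(
    frame: np.ndarray,
    roi: CellROI,
    min_area_px: int = 9,
    closing_radius: int = 2,
    pixel_size_um: float = 0.11,
) -> SegmentationMask:
    """Segment vacuole lumina inside a cell ROI.

    The membrane signal is thresholded (Otsu on the ROI), morphologically
    closed, and the complement is labeled with 4-connectivity.  Complement
    components containing an ROI corner pixel are treated as unenclosed
    cytoplasm/background and dropped (ROI corners sit in plasma-membrane
    territory, outside any vacuolar compartment); components smaller than
    ``min_area_px`` are removed; components touching the ROI border are
    retained but flagged.  A constant ROI yields an empty, flagged mask.
    """
    sub = np.asarray(frame, dtype=float)[
        roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width
    ]
    if sub.shape != (roi.height, roi.width):
        raise ValueError(f"ROI {roi.cell_id} exceeds frame bounds")
    if np.ptp(sub) == 0:
        return SegmentationMask(
            np.zeros(sub.shape, dtype=np.int32), pixel_size_um, degenerate=True
        )
    membrane = sub > threshold_otsu(sub)
    if closing_radius > 0:
        membrane = ndimage.binary_closing(
            membrane, structure=disk(closing_radius), border_value=0
        )
    lab, _ = ndimage.label(~membrane, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    h, w = lab.shape
    corner_labels = {lab[0, 0], lab[0, w - 1], lab[h - 1, 0], lab[h - 1, w - 1]} - {0}
    keep = []
    for lbl in range(1, lab.max() + 1):
        if lbl in corner_labels:
            continue
        area = int((lab == lbl).sum())
        if area >= min_area_px:
            keep.append(lbl)
    out = np.zeros_like(lab, dtype=np.int32)
    border_labels = set()
    for new, old in enumerate(keep, start=1):
        mask = lab == old
        out[mask] = new
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            border_labels.add(new)
    return SegmentationMask(out, pixel_size_um, border_labels=frozenset(border_labels))


def _feret_box(points: np.ndarray) -> tuple[float, float]:
    """(max Feret diameter, max extent perpendicular to it) of a point cloud."""
    if len(points) >= 4:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # collinear degenerate cloud
            pass
    best = (0.0, 0, 0)
    for i in range(len(points)):
        d = points[i + 1 :] - points[i]
        if len(d) == 0:
            continue
        dist2 = (d**2).sum(axis=1)
        j = int(np.argmax(dist2))
        if dist2[j] > best[0]:
            best = (float(dist2[j]), i, i + 1 + j)
    feret = math.sqrt(best[0])
    if feret == 0:
        return 0.0, 0.0
    u = (points[best[2]] - points[best[1]]) / feret
    perp = np.array([-u[1], u[0]])
    proj = points @ perp
    return feret, float(proj.max() - proj.min())


def compute_vmi(mask: SegmentationMask, strategy: str = "feret") -> tuple[float, float]:
    """VMI of the largest-area compartment, with its natural log.

    ``strategy='feret'`` (default): maximal Feret diameter x maximal
    perpendicular extent, both in um.  ``strategy='area'``: plain area of the
    largest compartment in um^2.  Raises if the mask holds no compartment.
    """
    if mask.n_compartments == 0:
        raise ValueError("no compartments in segmentation mask")
    areas = ndimage.sum_labels(
        np.ones_like(mask.labels), mask.labels, index=range(1, mask.n_compartments + 1)
    )
    largest = int(np.argmax(areas)) + 1
    ys, xs = np.nonzero(mask.labels == largest)
    if strategy == "area":
        vmi = float(areas[largest - 1]) * mask.pixel_size_um**2
    elif strategy == "feret":
        pts = np.stack([xs, ys], axis=1).astype(float)
        feret, perp = _feret_box(pts)
        # Extents over pixel centers; floor at 1 px so a single-pixel-wide
        # region still has the physical thickness of one pixel.
        vmi = max(feret, 1.0) * max(perp, 1.0) * mask.pixel_size_um**2
    else:
        raise ValueError("strategy must be 'feret' or 'area'")
    if vmi <= 0:
        raise ValueError("degenerate compartment: non-positive VMI")
    return vmi, math.log(vmi)


def transect_profile(
    frame: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step_px: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Linearly interpolated intensity profile along a segment.

    Returns (profile, segment length in px).  Sampling spacing is at most
    ``step_px``.
    """
    x0, y0 = p0
    x1, y1 = p1
    length = math.hypot(x1 - x0, y1 - y0)
    n = max(2, int(math.ceil(length / step_px)) + 1)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    prof = ndimage.map_coordinates(
        np.asarray(frame, dtype=float), np.stack([ys, xs]), order=1, mode="nearest"
    )
    return prof, length


def profile_threshold(profile: np.ndarray) -> tuple[float, float]:
    """(membrane, lumen) thresholds for a transect intensity profile.

    A transect typically samples three intensity classes — lumen,
    cytoplasm/background, and membrane — so a 3-class Otsu yields the
    membrane threshold (upper) and the lumen threshold (lower); profiles
    with fewer distinct levels fall back to 2-class Otsu for both.
    """
    profile = np.asarray(profile, dtype=float)
    try:
        lo, hi = threshold_multiotsu(profile, classes=3)
        return float(hi), float(lo)
    except ValueError:
        t = float(threshold_otsu(profile))
        return t, t


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) indices of maximal True runs."""
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts, ends))


def count_crossings(
    profile: np.ndarray, membrane_threshold: float, lumen_threshold: float | None = None
) -> int:
    """Tonoplast crossings along a binarized transect profile.

    The profile is segmented into membrane runs (above
    ``membrane_threshold``) and gaps; a gap is a vacuole lumen if its
    minimum reaches ``lumen_threshold``.  Every interior lumen gap that is
    flanked on both sides by membrane runs — neither of which contains a
    transect endpoint — represents a traversed compartment and contributes
    two crossings (entry plus exit).  Tangential grazes of a membrane
    (cytoplasm on both sides) count zero, and anything touching a transect
    endpoint is plasma-membrane territory and is excluded, so the total is
    structurally even.
    """
    prof = np.asarray(profile, dtype=float)
    if lumen_threshold is None:
        lumen_threshold = membrane_threshold
    membrane = prof > membrane_threshold
    runs = _runs(membrane)
    n = len(prof)
    crossings = 0
    for left, right in zip(runs[:-1], runs[1:]):
        if left[0] == 0 or right[1] == n:
            continue  # flanking run touches a transect endpoint
        gap = prof[left[1] : right[0]]
        if len(gap) and gap.min() <= lumen_threshold:
            crossings += 2
    return crossings


def compute_tti(
    frame: np.ndarray,
    roi: CellROI,
    pixel_size_um: float = 0.11,
    diagonal: str = "tl-br",
    step_px: float = 0.5,
    threshold: float | None = None,
) -> TTIResult:
    """Tonoplast topology index: membrane crossings per um of a diagonal transect.

    The transect runs corner to corner of the ROI (pixel centers); the
    intensity profile is thresholded (default: :func:`profile_threshold` on
    the profile; an explicit ``threshold`` is used for both membrane and
    lumen levels) and crossings are counted per :func:`count_crossings`,
    with endpoint-touching membrane runs excluded as plasma-membrane
    contacts.  ``diagonal='both'`` averages the two diagonals.
    """
    if diagonal == "both":
        a = compute_tti(frame, roi, pixel_size_um, "tl-br", step_px, threshold)
        b = compute_tti(frame, roi, pixel_size_um, "tr-bl", step_px, threshold)
        return TTIResult(
            crossings=(a.crossings + b.crossings) / 2.0,
            transect_length_um=(a.transect_length_um + b.transect_length_um) / 2.0,
            tti_per_um=(a.tti_per_um + b.tti_per_um) / 2.0,
            degenerate=a.degenerate or b.degenerate,
        )
    x0, y0, w, h = roi.rect
    if diagonal == "tl-br":
        p0, p1 = (x0, y0), (x0 + w - 1, y0 + h - 1)
    elif diagonal == "tr-bl":
        p0, p1 = (x0 + w - 1, y0), (x0, y0 + h - 1)
    else:
        raise ValueError("diagonal must be 'tl-br', 'tr-bl' or 'both'")
    prof, length_px = transect_profile(frame, p0, p1, step_px)
    length_um = length_px * pixel_size_um
    degenerate = False
    if threshold is None:
        if np.ptp(prof) == 0:
            return TTIResult(0.0, length_um, 0.0, degenerate=True)
        t_membrane, t_lumen = profile_threshold(prof)
    else:
        t_membrane = t_lumen = float(threshold)
    crossings = count_crossings(prof, t_membrane, t_lumen)
    return TTIResult(float(crossings), length_um, crossings / length_um, degenerate)


def morphology_table(
    frame: np.ndarray,
    rois: list[CellROI],
    pixel_size_um: float = 0.11,
    vmi_strategy: str = "feret",
    diagonal: str = "tl-br",
    min_area_px: int = 9,
) -> pd.DataFrame:
    """Per-cell VMI/TTI table for one frame and a set of cell ROIs.

    Per-cell failures (empty segmentation, degenerate thresholds, bad ROIs)
    are recorded in the ``flags`` column rather than aborting the batch.
    """
    records: list[MorphologyRecord] = []
    for roi in rois:
        rec = MorphologyRecord(
            cell_id=roi.cell_id,
            condition_label=roi.condition_label,
            length_um=roi.length_um(pixel_size_um),
            root_surface=roi.root_surface,
        )
        flags: list[str] = []
        try:
            mask = segment_lumen(
                frame, roi, min_area_px=min_area_px, pixel_size_um=pixel_size_um
            )
            rec.n_compartments = mask.n_compartments
            if mask.degenerate:
                flags.append("degenerate_threshold")
            if mask.border_labels:
                flags.append("border_compartment")
            if mask.n_compartments == 0:
                flags.append("no_compartment")
            else:
                rec.vmi_um2, rec.ln_vmi = compute_vmi(mask, strategy=vmi_strategy)
        except ValueError as exc:
            flags.append(f"vmi_failed:{exc}")
        try:
            tti = compute_tti(frame, roi, pixel_size_um, diagonal=diagonal)
            rec.crossings = tti.crossings
            rec.transect_length_um = tti.transect_length_um
            rec.tti_per_um = tti.tti_per_um
            if tti.degenerate:
                flags.append("tti_degenerate")
        except ValueError as exc:
            flags.append(f"tti_failed:{exc}")
        rec.flags = ";".join(flags)
        records.append(rec)
    return pd.DataFrame([r.__dict__ for r in records])
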
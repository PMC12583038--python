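"""Synthetic tonoplast images and time-lapse movies with known ground truth.

The generator emulates what a membrane-localized vacuolar marker looks like
in a single confocal plane of root rhizodermis cells: dark vacuole lumina
bounded by bright, thin tonoplast membranes inside rectangular cells, with
the surrounding cytoplasm at an intermediate background level.  Two presets
bracket the biological contrast of interest:

* ``consolidated`` — 1-2 large compartments per cell (the morphologically
  advanced central vacuole of atrichoblasts / formin-impaired cells);
* ``fragmented`` — >= 6 smaller compartments (a convoluted, fragmented
  vacuome).

Compartments are discs deformed by a low-order radial harmonic, which gives
tunable membrane convolutedness with a minimal parameter set.  Time-lapse
simulation adds slow rigid growth drift, smooth stochastic membrane motion
of controllable amplitude, photobleaching, and shot/read noise; every run
emits ground-truth tables (per-cell geometry, per-frame rigid transforms and
boundary displacements, lumen label images) so downstream measurements can
be validated quantitatively without any real recording.

Default study conditions: 0.11 um pixels, 2 s frame interval, 61 frames
(a 0-120 s analysis horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon
from skimage.morphology import disk

from .prep import Movie, RigidTransform, apply_rigid, _frame_center

DEFAULT_PIXEL_SIZE_UM = 0.11
DEFAULT_FRAME_INTERVAL_S = 2.0
DEFAULT_N_FRAMES = 61  # 0..120 s at 2 s per frame


class PackingError(RuntimeError):
    """Raised when compartments cannot be packed into a cell rectangle."""


@dataclass
class CellSpec:
    """Geometry and labeling of one synthetic cell.

    ``rect`` is (x0, y0, width, height) in pixels, half-open; compartment
    centers are absolute frame coordinates (x, y); radii are the base disc
    radii in pixels before harmonic deformation.
    """

    cell_id: str
    rect: tuple[int, int, int, int]
    length_um: float
    n_compartments: int
    compartment_centers: list[tuple[float, float]]
    compartment_radii: list[float]
    deform_amplitudes: list[float] = field(default_factory=list)
    deform_orders: list[int] = field(default_factory=list)
    deform_phases: list[float] = field(default_factory=list)
    condition_label: str = ""

    def __post_init__(self) -> None:
        n = self.n_compartments
        if n < 1 or len(self.compartment_centers) != n or len(self.compartment_radii) != n:
            raise ValueError("n_compartments must match centers and radii")
        if not self.deform_amplitudes:
            self.deform_amplitudes = [0.0] * n
        if not self.deform_orders:
            self.deform_orders = [3] * n
        if not self.deform_phases:
            self.deform_phases = [0.0] * n

    def validate(self, margin_px: float, membrane_thickness_px: float) -> None:
        x0, y0, w, h = self.rect
        for (cx, cy), r, a in zip(
            self.compartment_centers, self.compartment_radii, self.deform_amplitudes
        ):
            if r <= membrane_thickness_px:
                raise ValueError(f"{self.cell_id}: radius {r} <= membrane thickness")
            reach = r * (1 + a) + membrane_thickness_px
            if not (
                x0 + margin_px + reach <= cx <= x0 + w - margin_px - reach
                and y0 + margin_px + reach <= cy <= y0 + h - margin_px - reach
            ):
                raise ValueError(f"{self.cell_id}: compartment violates rect margin")


@dataclass
class OpticsNoiseSpec:
    """Rendering and acquisition-noise parameters (arbitrary intensity units).

    ``poisson_gain`` is photons per intensity unit (0 disables shot noise);
    ``gaussian_sigma`` is additive read noise; ``bleach_rate`` is the
    per-frame multiplicative intensity decay in [0, 1).
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    membrane_thickness_px: float = 2.0
    membrane_intensity: float = 200.0
    lumen_intensity: float = 15.0
    background_intensity: float = 40.0
    psf_sigma_px: float = 1.2
    poisson_gain: float = 6.0
    gaussian_sigma: float = 2.5
    bleach_rate: float = 0.002

    def __post_init__(self) -> None:
        if not (self.membrane_intensity > self.background_intensity >= self.lumen_intensity >= 0):
            raise ValueError("need membrane > background >= lumen >= 0")
        if self.psf_sigma_px < 0 or not (0 <= self.bleach_rate < 1):
            raise ValueError("invalid psf_sigma_px or bleach_rate")

    def noiseless(self) -> "OpticsNoiseSpec":
        from dataclasses import replace

        return replace(self, poisson_gain=0.0, gaussian_sigma=0.0, bleach_rate=0.0)


@dataclass
class MotionSpec:
    """Time-lapse motion parameters.

    ``drift_per_frame`` is the slow rigid growth drift (dx px, dy px,
    rotation degrees) accumulated each frame.  ``membrane_speed`` (px/frame)
    sets the amplitude of the smooth stochastic displacement of compartment
    boundaries: each boundary follows a smooth Gaussian process (3-frame
    temporal correlation length) whose RMS displacement from the initial
    position grows monotonically and saturates at
    ``displacement_scale_px * membrane_speed`` with relaxation time
    ``relaxation_frames`` — bounded wandering rather than an unbounded
    random walk, so that a grid of speeds maps onto a graded (not uniformly
    saturated) correlation decay over the 120-s horizon.
    """

    n_frames: int = DEFAULT_N_FRAMES
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    membrane_speed: float = 1.0
    seed: int = 0
    displacement_scale_px: float = 2.5
    relaxation_frames: float = 30.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.membrane_speed < 0:
            raise ValueError("membrane_speed must be >= 0")


@dataclass
class GeometryParams:
    """Population-level cell geometry (pixels unless noted)."""

    cell_width_px: tuple[int, int] = (100, 140)
    cell_length_px: tuple[int, int] = (180, 410)
    margin_px: float = 5.0
    min_gap_px: float = 5.0
    membrane_thickness_px: float = 2.0


#: Preset definitions: compartment count range, radius as a fraction of the
#: feasible maximum (consolidated) or absolute px range (fragmented), and the
#: harmonic deformation ranges.
PRESETS = {
    "consolidated": {
        "n_compartments": (1, 2),
        "radius_frac": (0.62, 0.88),
        "deform_amp": (0.02, 0.08),
        "deform_order": (2, 3),
    },
    "fragmented": {
        "n_compartments": (9, 14),
        "radius_px": (12.0, 22.0),
        "deform_amp": (0.06, 0.16),
        "deform_order": (2, 5),
    },
}


def _pack_compartments(
    rng: np.random.Generator,
    rect: tuple[int, int, int, int],
    n: int,
    radii: np.ndarray,
    amps: np.ndarray,
    geometry: GeometryParams,
    max_rounds: int = 12,
    tries_per_round: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Place ``n`` non-overlapping compartments inside ``rect``.

    Retries with radii shrunk by 10% per round; raises :class:`PackingError`
    if no feasible placement is found within the retry budget.
    """
    x0, y0, w, h = rect
    thick = geometry.membrane_thickness_px
    radii = radii.astype(float).copy()
    for _ in range(max_rounds):
        reach = radii * (1 + amps) + thick
        lo_x, hi_x = x0 + geometry.margin_px + reach, x0 + w - geometry.margin_px - reach
        lo_y, hi_y = y0 + geometry.margin_px + reach, y0 + h - geometry.margin_px - reach
        if np.any(lo_x >= hi_x) or np.any(lo_y >= hi_y):
            radii *= 0.9
            continue
        centers: list[tuple[float, float]] = []
        for i in range(n):
            placed = False
            for _ in range(tries_per_round):
                cx = rng.uniform(lo_x[i], hi_x[i])
                cy = rng.uniform(lo_y[i], hi_y[i])
                ok = True
                for j, (px, py) in enumerate(centers):
                    min_d = reach[i] + reach[j] + geometry.min_gap_px
                    if (cx - px) ** 2 + (cy - py) ** 2 < min_d**2:
                        ok = False
                        break
                if ok:
                    centers.append((cx, cy))
                    placed = True
                    break
            if not placed:
                break
        if len(centers) == n:
            return np.array(centers), radii
        radii *= 0.9
    raise PackingError(f"cannot pack {n} compartments into rect {rect}")


def generate_cell_population(
    n_cells: int,
    preset: str = "consolidated",
    seed: int = 0,
    *,
    geometry: GeometryParams | None = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    condition_label: str | None = None,
    layout: str = "separate",
    grid_cols: int = 8,
    grid_pad_px: int = 6,
) -> list[CellSpec]:
    """Draw ``n_cells`` reproducible cell geometries from a preset.

    ``layout='separate'`` places every cell rect at the origin (each cell is
    rendered in its own frame/movie); ``layout='grid'`` tiles the rects on a
    shared canvas so one frame can hold the whole population.  Cell lengths
    are uniform over ``geometry.cell_length_px``; widths uniform over
    ``geometry.cell_width_px``.  Consolidated cells get 1-2 compartments,
    fragmented cells >= 6, per the preset table.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    geometry = geometry or GeometryParams()
    label = preset if condition_label is None else condition_label
    rng = np.random.default_rng(seed)

    cells: list[CellSpec] = []
    for i in range(n_cells):
        w = int(rng.integers(geometry.cell_width_px[0], geometry.cell_width_px[1] + 1))
        h = int(rng.integers(geometry.cell_length_px[0], geometry.cell_length_px[1] + 1))
        if layout == "grid":
            col = i % grid_cols
            row = i // grid_cols
            x0 = grid_pad_px + col * (geometry.cell_width_px[1] + 2 * grid_pad_px)
            y0 = grid_pad_px + row * (geometry.cell_length_px[1] + 2 * grid_pad_px)
        elif layout == "separate":
            x0, y0 = 0, 0
        else:
            raise ValueError("layout must be 'separate' or 'grid'")
        rect = (x0, y0, w, h)

        n_comp = int(rng.integers(p["n_compartments"][0], p["n_compartments"][1] + 1))
        amps = rng.uniform(*p["deform_amp"], size=n_comp)
        orders = rng.integers(p["deform_order"][0], p["deform_order"][1] + 1, size=n_comp)
        phases = rng.uniform(0, 2 * np.pi, size=n_comp)
        if "radius_frac" in p:
            r_cap = min(w, h) / 2 - geometry.margin_px - geometry.membrane_thickness_px
            radii = rng.uniform(*p["radius_frac"], size=n_comp) * r_cap / (1 + amps)
        else:
            radii = rng.uniform(*p["radius_px"], size=n_comp)
        centers, radii = _pack_compartments(rng, rect, n_comp, radii, amps, geometry)

        cells.append(
            CellSpec(
                cell_id=f"{label}_{i:03d}",
                rect=rect,
                length_um=h * pixel_size_um,
                n_compartments=n_comp,
                compartment_centers=[tuple(c) for c in centers],
                compartment_radii=list(radii),
                deform_amplitudes=list(amps),
                deform_orders=[int(o) for o in orders],
                deform_phases=list(phases),
                condition_label=label,
            )
        )
    return cells


def _canvas_shape(cells: Sequence[CellSpec], pad: int = 4) -> tuple[int, int]:
    xmax = max(c.rect[0] + c.rect[2] for c in cells)
    ymax = max(c.rect[1] + c.rect[3] for c in cells)
    return (ymax + pad, xmax + pad)


def _boundary_polygon(
    center: tuple[float, float], r0: float, amp: float, order: int, phase: float,
    n_vertices: int = 180,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertices (x, y) of a harmonically deformed disc boundary."""
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = r0 * (1 + amp * np.cos(order * phi + phase))
    return center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)


def _paint_cells(
    cells: Sequence[CellSpec],
    optics: OpticsNoiseSpec,
    shape: tuple[int, int],
    centers_override: np.ndarray | None = None,
    phases_override: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize lumina and membrane bands; returns (intensity, label image)."""
    img = np.full(shape, optics.background_intensity, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    selem = disk(max(1, int(round(optics.membrane_thickness_px))))
    lab = 0
    idx = 0
    for cell in cells:
        for k in range(cell.n_compartments):
            lab += 1
            cx, cy = (
                tuple(centers_override[idx])
                if centers_override is not None
                else cell.compartment_centers[k]
            )
            phase = (
                float(phases_override[idx])
                if phases_override is not None
                else cell.deform_phases[k]
            )
            idx += 1
            xs, ys = _boundary_polygon(
                (cx, cy), cell.compartment_radii[k], cell.deform_amplitudes[k],
                cell.deform_orders[k], phase,
            )
            rr, cc = _draw_polygon(ys, xs, shape)
            lumen = np.zeros(shape, dtype=bool)
            lumen[rr, cc] = True
            band = ndimage.binary_dilation(lumen, structure=selem) & ~lumen
            img[band] = optics.membrane_intensity
            img[lumen] = optics.lumen_intensity
            labels[lumen] = lab
    return img, labels


def render_frame(
    cells: Sequence[CellSpec],
    optics: OpticsNoiseSpec | None = None,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame plus its ground-truth lumen label image.

    Membranes are bright ridges of ``membrane_thickness_px`` around each
    compartment; the label image marks each lumen with a unique positive
    integer.  Blur (PSF) and noise are applied to the intensity image only.
    Deterministic for fixed ``(cells, optics, seed)``.
    """
    optics = optics or OpticsNoiseSpec()
    for c in cells:
        c.validate(margin_px=0.0, membrane_thickness_px=optics.membrane_thickness_px)
    shape = shape or _canvas_shape(cells)
    img, labels = _paint_cells(cells, optics, shape)
    if optics.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, optics.psf_sigma_px)
    rng = np.random.default_rng(seed)
    img = _apply_noise(img, optics, rng)
    return img, labels


def _apply_noise(img: np.ndarray, optics: OpticsNoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if optics.poisson_gain > 0:
        img = rng.poisson(np.clip(img, 0, None) * optics.poisson_gain) / optics.poisson_gain
    if optics.gaussian_sigma > 0:
        img = img + rng.normal(0.0, optics.gaussian_sigma, img.shape)
    return img


def simulate_timelapse(
    cells: Sequence[CellSpec],
    optics: OpticsNoiseSpec | None = None,
    motion: MotionSpec | None = None,
    shape: tuple[int, int] | None = None,
    keep_labels: bool = True,
) -> tuple[Movie, dict]:
    """Simulate a time-lapse movie with drift, membrane motion, bleach, noise.

    Frame ``k`` is rendered after (1) displacing each compartment center by a
    smoothed Gaussian random walk with per-step RMS ``membrane_speed`` px and
    a 3-frame temporal correlation length (deformation phases drift with the
    same process), and (2) applying the cumulative rigid growth drift
    ``k * drift_per_frame``.  Compartments that would leave the cell rect are
    clamped, counted in ``ground_truth['clamp_events']``.

    Returns ``(movie, ground_truth)`` where ground truth holds per-frame
    cumulative transforms ``(dx, dy, theta_deg)``, per-frame mean boundary
    step and cumulative displacement (px), per-cell geometry, and (when
    ``keep_labels``) the per-frame lumen label stack.
    """
    optics = optics or OpticsNoiseSpec()
    motion = motion or MotionSpec()
    shape = shape or _canvas_shape(cells)
    rng = np.random.default_rng(motion.seed)
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))

    n_comp = sum(c.n_compartments for c in cells)
    T = motion.n_frames
    # Smooth stationary unit GP (3-frame correlation length) modulated by a
    # monotone envelope sqrt(1 - exp(-2t/tau)): displacement starts at zero,
    # its RMS grows monotonically and saturates at the amplitude below.
    amplitude = motion.displacement_scale_px * motion.membrane_speed
    u = rng.normal(0.0, 1.0, size=(T, n_comp, 2))
    phase_u = rng.normal(0.0, 1.0, size=(T, n_comp))
    if amplitude > 0 and T > 1:
        u = ndimage.gaussian_filter1d(u, sigma=3.0, axis=0, mode="nearest")
        u /= max(u.std(), 1e-12)
        envelope = np.sqrt(1.0 - np.exp(-2.0 * np.arange(T) / motion.relaxation_frames))
        offsets = amplitude * envelope[:, None, None] * u
        phase_u = ndimage.gaussian_filter1d(phase_u, sigma=3.0, axis=0, mode="nearest")
        phase_u /= max(phase_u.std(), 1e-12)
        phase_offsets = 0.1 * motion.membrane_speed * envelope[:, None] * phase_u
    else:
        offsets = np.zeros((T, n_comp, 2))
        phase_offsets = np.zeros((T, n_comp))

    base_centers = np.array(
        [c.compartment_centers[k] for c in cells for k in range(c.n_compartments)]
    )
    base_phases = np.array(
        [c.deform_phases[k] for c in cells for k in range(c.n_compartments)]
    )
    # Per-compartment clamp box keeping the deformed disc + membrane in-rect.
    lo = np.empty_like(base_centers)
    hi = np.empty_like(base_centers)
    idx = 0
    for c in cells:
        x0, y0, w, h = c.rect
        for k in range(c.n_compartments):
            reach = (
                c.compartment_radii[k] * (1 + c.deform_amplitudes[k])
                + optics.membrane_thickness_px + 1.0
            )
            lo[idx] = (x0 + reach, y0 + reach)
            hi[idx] = (x0 + w - reach, y0 + h - reach)
            idx += 1

    center = _frame_center(shape)
    ddx, ddy, dth = motion.drift_per_frame
    frames = np.empty((T,) + shape, dtype=float)
    label_stack = np.empty((T,) + shape, dtype=np.int32) if keep_labels else None
    transforms: list[tuple[float, float, float]] = []
    mean_step = np.zeros(T)
    mean_cum = np.zeros(T)
    clamp_events = 0
    prev_centers = base_centers.copy()
    for t in range(T):
        centers_t = base_centers + offsets[t]
        clamped = np.clip(centers_t, lo, hi)
        clamp_events += int(np.any(clamped != centers_t, axis=1).sum())
        centers_t = clamped
        mean_step[t] = 0.0 if t == 0 else float(
            np.mean(np.linalg.norm(centers_t - prev_centers, axis=1))
        )
        mean_cum[t] = float(np.mean(np.linalg.norm(centers_t - base_centers, axis=1)))
        prev_centers = centers_t

        img, labels = _paint_cells(
            cells, optics, shape, centers_override=centers_t,
            phases_override=base_phases + phase_offsets[t],
        )
        if optics.psf_sigma_px > 0:
            img = ndimage.gaussian_filter(img, optics.psf_sigma_px)
        tf = (ddx * t, ddy * t, dth * t)
        transforms.append(tf)
        if any(abs(v) > 0 for v in tf):
            rigid = RigidTransform(tf[0], tf[1], tf[2], center)
            img = apply_rigid(img, rigid, order=1, cval=optics.background_intensity)
            if keep_labels:
                labels = apply_rigid(labels, rigid, order=0, cval=0.0).astype(np.int32)
        img = img * (1.0 - optics.bleach_rate) ** t
        frames[t] = _apply_noise(img, optics, noise_rng)
        if keep_labels:
            label_stack[t] = labels

    movie = Movie(
        frames=frames,
        frame_interval_s=motion.frame_interval_s,
        pixel_size_um=optics.pixel_size_um,
    )
    ground_truth = {
        "transforms": transforms,
        "mean_step_px": mean_step,
        "mean_cum_disp_px": mean_cum,
        "clamp_events": clamp_events,
        "cells": list(cells),
        "labels": label_stack,
    }
    return movie, ground_truth


def noise_movie(
    shape: tuple[int, int] = (32, 32),
    n_frames: int = DEFAULT_N_FRAMES,
    seed: int = 0,
    sigma: float = 20.0,
    mean: float = 100.0,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> Movie:
    """Movie of independent pure-Gaussian-noise frames (noise-only preset)."""
    rng = np.random.default_rng(seed)
    frames = rng.normal(mean, sigma, size=(n_frames,) + shape)
    return Movie(frames, frame_interval_s=frame_interval_s, pixel_size_um=pixel_size_um)
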
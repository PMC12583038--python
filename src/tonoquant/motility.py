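"""Rapid tonoplast motility from frame-to-first-frame intensity correlation.

Motility of the tonoplast (driven by cytoplasmic streaming) is quantified
per cell as the decay over time of the Pearson correlation coefficient R
between the pixel intensities of a movie's first frame and every later
frame of the preprocessed, per-cell-cropped recording.  The endpoint
statistic ``r_end`` is R at the frame nearest a 120-s horizon.  A slowly
rearranging tonoplast keeps R near 1; vigorous membrane motion decorrelates
the frames and drives R down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import Movie


@dataclass
class MotilityCurve:
    """Per-cell R(t) curve.

    ``r_values[0]`` is identically 1 (first frame against itself); ``r_end``
    is R at the frame nearest the analysis horizon, flagged ``truncated``
    when the movie is shorter than the horizon.
    """

    cell_id: str
    condition_label: str
    length_um: float
    times_s: np.ndarray
    r_values: np.ndarray
    r_end: float
    truncated: bool = False


def frame_correlation(
    frame_a: np.ndarray, frame_b: np.ndarray, window_px: int | str = "full"
) -> float:
    """Pearson correlation R between two frames.

    With ``window_px='full'`` the two pixel-intensity vectors are correlated
    globally.  With an integer window ``w`` the frames are tiled into
    non-overlapping w x w blocks (partial edge blocks discarded), Pearson is
    computed per block, and the unweighted mean over blocks with defined
    variance in both frames is returned (zero-variance blocks are skipped so
    undefined correlations do not bias the mean).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have identical shapes")
    if window_px == "full":
        r = _pearson(a.ravel(), b.ravel())
        if r is None:
            raise ValueError("zero variance: correlation undefined")
        return r
    w = int(window_px)
    if w < 2 or w > min(a.shape):
        raise ValueError("window_px must be in [2, min(frame shape)]")
    rs = []
    for i in range(0, a.shape[0] - w + 1, w):
        for j in range(0, a.shape[1] - w + 1, w):
            r = _pearson(a[i : i + w, j : j + w].ravel(), b[i : i + w, j : j + w].ravel())
            if r is not None:
                rs.append(r)
    if not rs:
        raise ValueError("zero variance in every block: correlation undefined")
    return float(np.mean(rs))


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return None
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def motility_curve(
    movie: Movie,
    cell_id: str = "",
    condition_label: str = "",
    window_px: int | str = "full",
    horizon_s: float = 120.0,
) -> MotilityCurve:
    """R(t) of every frame against the (duplicated) first frame.

    The movie is expected to be preprocessed (contrast-enhanced, registered,
    cropped to one cell).  ``r_end`` is taken at the frame nearest
    ``horizon_s``; when the recording is shorter than the horizon the last
    frame is used and the curve is flagged truncated.
    """
    times = movie.times_s
    first = movie.frames[0]
    r = np.empty(movie.n_frames)
    for k in range(movie.n_frames):
        r[k] = frame_correlation(first, movie.frames[k], window_px)
    truncated = times[-1] < horizon_s
    end_idx = int(np.argmin(np.abs(times - horizon_s)))
    return MotilityCurve(
        cell_id=cell_id,
        condition_label=condition_label,
        length_um=movie.frames.shape[1] * movie.pixel_size_um,
        times_s=times,
        r_values=r,
        r_end=float(r[end_idx]),
        truncated=truncated,
    )


def average_curves(curves: list[MotilityCurve]) -> pd.DataFrame:
    """Group-mean R(t) with SEM, grouped by condition label.

    All curves must share the same time grid.  Returns a tidy frame with
    columns ``group, t_s, mean_r, sem_r, n``; SEM is the sample standard
    deviation over cells divided by sqrt(n) and is NaN for n = 1.
    """
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].times_s
    for c in curves[1:]:
        if len(c.times_s) != len(t0) or not np.allclose(c.times_s, t0):
            raise ValueError("curves have mismatched time grids")
    rows = []
    groups: dict[str, list[MotilityCurve]] = {}
    for c in curves:
        groups.setdefault(c.condition_label, []).append(c)
    for g, cs in groups.items():
        R = np.stack([c.r_values for c in cs])
        mean = R.mean(axis=0)
        n = len(cs)
        sem = R.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(t0), np.nan)
        for k in range(len(t0)):
            rows.append(
                {"group": g, "t_s": t0[k], "mean_r": mean[k], "sem_r": sem[k], "n": n}
            )
    return pd.DataFrame(rows)


def kymograph(
    movie: Movie,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step_px: float = 1.0,
) -> np.ndarray:
    """Position x time image along a fixed line segment.

    Row ``t`` is the linearly interpolated intensity profile along the
    segment (from ``p0`` to ``p1``, in (x, y) pixel coordinates) in frame
    ``t``; the output has ``n_frames`` rows and ``ceil(length / step_px)``
    columns.  Raises if the segment leaves the frame.
    """
    from scipy import ndimage

    h, w = movie.shape
    for (x, y) in (p0, p1):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"segment endpoint {(x, y)} outside frame {(h, w)}")
    length = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    n = max(1, int(np.ceil(length / step_px)))
    ux, uy = (p1[0] - p0[0]) / length, (p1[1] - p0[1]) / length
    k = np.arange(n) * step_px
    xs = p0[0] + k * ux
    ys = p0[1] + k * uy
    out = np.empty((movie.n_frames, n))
    for t in range(movie.n_frames):
        out[t] = ndimage.map_coordinates(
            np.asarray(movie.frames[t], dtype=float), np.stack([ys, xs]), order=1,
            mode="nearest",
        )
    return out
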
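"""Vacuole morphometry: segmentation, VMI (Feret box), TTI (transect crossings)."""

import itertools
import math

import numpy as np
import pytest

from tonoquant import synthetic
from tonoquant.morphology import (
    SegmentationMask,
    compute_tti,
    compute_vmi,
    morphology_table,
    segment_lumen,
    transect_profile,
)
from tonoquant.prep import CellROI
from tonoquant.synthetic import CellSpec, generate_cell_population, render_frame

from conftest import roi_of


def brute_force_feret_box(points: np.ndarray) -> float:
    """Oracle: exhaustive calipers over all point pairs (not just hull)."""
    best_d2, pair = 0.0, None
    for i, j in itertools.combinations(range(len(points)), 2):
        d2 = float(((points[i] - points[j]) ** 2).sum())
        if d2 > best_d2:
            best_d2, pair = d2, (i, j)
    feret = math.sqrt(best_d2)
    u = (points[pair[1]] - points[pair[0]]) / feret
    proj = points @ np.array([-u[1], u[0]])
    return feret * (proj.max() - proj.min())


def count_crossings_oracle(prof, t_membrane, t_lumen) -> int:
    """Independent sample-by-sample scan of a transect profile.

    Segments the profile into membrane runs and gaps, then awards two
    crossings for every lumen-deep gap enclosed between two membrane runs
    that stay clear of the profile ends.
    """
    segments = []  # (is_membrane, min_value, touches_start, touches_end)
    cur_kind = prof[0] > t_membrane
    cur_min, cur_start = prof[0], 0
    for i in range(1, len(prof)):
        kind = prof[i] > t_membrane
        if kind != cur_kind:
            segments.append((cur_kind, cur_min, cur_start == 0, False))
            cur_kind, cur_min, cur_start = kind, prof[i], i
        else:
            cur_min = min(cur_min, prof[i])
    segments.append((cur_kind, cur_min, cur_start == 0, True))
    total = 0
    for i, (is_mem, vmin, at_start, at_end) in enumerate(segments):
        if is_mem or at_start or at_end or vmin > t_lumen:
            continue
        left, right = segments[i - 1], segments[i + 1]
        if left[0] and right[0] and not left[2] and not right[3]:
            total += 2
    return total


class TestSegmentation:
    def test_single_compartment_recovered_with_area(self, optics_clean, one_compartment_cell):
        frame, labels = render_frame([one_compartment_cell], optics_clean, seed=0)
        mask = segment_lumen(frame, roi_of(one_compartment_cell))
        assert mask.n_compartments == 1
        gt_area = int((labels == 1).sum())
        est_area = int((mask.labels > 0).sum())
        assert est_area == pytest.approx(gt_area, rel=0.05)

    def test_constant_roi_gives_empty_flagged_mask(self):
        frame = np.full((64, 64), 5.0)
        mask = segment_lumen(frame, CellROI("c", 0, 0, 32, 32))
        assert mask.n_compartments == 0 and mask.degenerate

    def test_eight_compartments_recovered(self, optics_clean):
        rng = np.random.default_rng(12)
        centers = [(c % 2 * 60 + 40, c // 2 * 60 + 40) for c in range(8)]
        cell = CellSpec(
            "c8", (0, 0, 140, 260), 260 * 0.11, 8,
            compartment_centers=[(float(x), float(y)) for x, y in centers],
            compartment_radii=[16.0] * 8,
            deform_amplitudes=list(rng.uniform(0.05, 0.1, 8)),
        )
        frame, _ = render_frame([cell], optics_clean, seed=0)
        mask = segment_lumen(frame, roi_of(cell))
        assert mask.n_compartments == 8

    def test_recovery_under_default_noise(self, optics):
        cells = generate_cell_population(5, "fragmented", seed=21)
        for i, c in enumerate(cells):
            frame, _ = render_frame([c], optics, seed=50 + i)
            mask = segment_lumen(frame, roi_of(c))
            assert mask.n_compartments == c.n_compartments


class TestVMI:
    def test_rasterized_disc_matches_analytic_square(self):
        # disc radius 20 px at 0.1 um/px: Feret box is (2r)^2 px^2 -> 16 um^2
        yy, xx = np.mgrid[:64, :64]
        labels = (((xx - 32) ** 2 + (yy - 32) ** 2) <= 20**2).astype(np.int32)
        vmi, ln_vmi = compute_vmi(SegmentationMask(labels, pixel_size_um=0.1))
        assert vmi == pytest.approx(16.0, rel=0.05)
        assert ln_vmi == pytest.approx(math.log(vmi))

    def test_thin_rectangle_matches_brute_force_calipers(self):
        labels = np.zeros((40, 120), dtype=np.int32)
        labels[10:20, 5:105] = 1  # 100 x 10 px at 0.1 um/px: 10 x 1 um
        mask = SegmentationMask(labels, pixel_size_um=0.1)
        vmi, _ = compute_vmi(mask)
        ys, xs = np.nonzero(labels)
        # oracle works on the region outline only, to stay tractable
        edge = (xs == xs.min()) | (xs == xs.max()) | (ys == ys.min()) | (ys == ys.max())
        pts = np.stack([xs[edge], ys[edge]], 1).astype(float)
        oracle = brute_force_feret_box(pts)
        assert vmi == pytest.approx(oracle * 0.1 * 0.1, rel=0.05)

    def test_largest_compartment_selected(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[2:22, 2:22] = 1  # 400 px
        labels[30:35, 30:35] = 2  # 25 px
        vmi_both, _ = compute_vmi(SegmentationMask(labels, 1.0))
        only = np.where(labels == 1, 1, 0).astype(np.int32)
        vmi_largest, _ = compute_vmi(SegmentationMask(only, 1.0))
        assert vmi_both == vmi_largest

    def test_scaling_multiplies_vmi_quadratically(self):
        yy, xx = np.mgrid[:200, :200]
        small = (((xx - 100) ** 2 + (yy - 100) ** 2) <= 20**2).astype(np.int32)
        big = (((xx - 100) ** 2 + (yy - 100) ** 2) <= 60**2).astype(np.int32)
        v_small, _ = compute_vmi(SegmentationMask(small, 1.0))
        v_big, _ = compute_vmi(SegmentationMask(big, 1.0))
        assert v_big == pytest.approx(9 * v_small, rel=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no compartments"):
            compute_vmi(SegmentationMask(np.zeros((8, 8), dtype=np.int32), 1.0))

    def test_area_strategy_returns_plain_area(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[5:15, 5:15] = 1
        vmi, _ = compute_vmi(SegmentationMask(labels, 0.5), strategy="area")
        assert vmi == pytest.approx(100 * 0.25)


class TestTTI:
    def test_single_centered_compartment_crosses_twice(self, optics_clean, one_compartment_cell):
        frame, _ = render_frame([one_compartment_cell], optics_clean, seed=0)
        res = compute_tti(frame, roi_of(one_compartment_cell), optics_clean.pixel_size_um)
        assert res.crossings == 2
        diag_um = math.hypot(one_compartment_cell.rect[2] - 1,
                             one_compartment_cell.rect[3] - 1) * optics_clean.pixel_size_um
        assert res.transect_length_um == pytest.approx(diag_um)
        assert res.tti_per_um == pytest.approx(2 / diag_um)

    def test_uniform_dark_roi_has_no_crossings(self):
        res = compute_tti(np.zeros((64, 64)), CellROI("c", 0, 0, 40, 40), 0.1)
        assert res.crossings == 0 and res.tti_per_um == 0

    def test_four_compartments_on_diagonal_cross_eight_times(self, optics_clean):
        n, size = 4, 400
        step = size / (n + 1)
        centers = [((k + 1) * step, (k + 1) * step) for k in range(n)]
        cell = CellSpec(
            "diag", (0, 0, size, size), size * 0.11, n,
            compartment_centers=centers, compartment_radii=[25.0] * n,
        )
        frame, _ = render_frame([cell], optics_clean, seed=0)
        res = compute_tti(frame, roi_of(cell), optics_clean.pixel_size_um)
        assert res.crossings == 2 * n

    def test_crossings_match_independent_run_scan(self, optics):
        from tonoquant.morphology import profile_threshold

        cells = generate_cell_population(30, "fragmented", seed=31)
        for i, c in enumerate(cells):
            frame, _ = render_frame([c], optics, seed=i)
            roi = roi_of(c)
            res = compute_tti(frame, roi, optics.pixel_size_um)
            x0, y0, w, h = roi.rect
            prof, _ = transect_profile(frame, (x0, y0), (x0 + w - 1, y0 + h - 1))
            t_mem, t_lum = profile_threshold(prof)
            assert res.crossings == count_crossings_oracle(prof, t_mem, t_lum)

    def test_crossings_even_for_interior_compartments(self, optics_clean):
        cells = generate_cell_population(20, "fragmented", seed=41)
        for c in cells:
            frame, _ = render_frame([c], optics_clean, seed=0)
            res = compute_tti(frame, roi_of(c), optics_clean.pixel_size_um)
            assert res.crossings % 2 == 0

    def test_both_diagonals_mode_averages(self, optics_clean, one_compartment_cell):
        frame, _ = render_frame([one_compartment_cell], optics_clean, seed=0)
        roi = roi_of(one_compartment_cell)
        a = compute_tti(frame, roi, 0.11, diagonal="tl-br")
        b = compute_tti(frame, roi, 0.11, diagonal="tr-bl")
        both = compute_tti(frame, roi, 0.11, diagonal="both")
        assert both.tti_per_um == pytest.approx((a.tti_per_um + b.tti_per_um) / 2)


class TestMorphologyTable:
    def test_one_record_per_cell(self, optics):
        cells = generate_cell_population(2, "consolidated", seed=51)
        shape = (
            max(c.rect[1] + c.rect[3] for c in cells) + 4,
            max(c.rect[0] + c.rect[2] for c in cells) + 4,
        )
        frame, _ = render_frame(cells, optics, seed=0, shape=shape)
        table = morphology_table(frame, [roi_of(c) for c in cells], 0.11)
        assert len(table) == 2
        assert table["vmi_um2"].notna().all()

    def test_failed_cell_recorded_not_fatal(self, optics):
        cells = generate_cell_population(1, "consolidated", seed=52)
        frame, _ = render_frame(cells, optics, seed=0)
        rois = [roi_of(cells[0]), CellROI("blank", 0, 0, 10, 10)]
        frame[:10, :10] = 3.0  # constant corner: degenerate segmentation
        table = morphology_table(frame, rois, 0.11)
        assert len(table) == 2
        failed = table[table.cell_id == "blank"].iloc[0]
        assert np.isnan(failed["vmi_um2"]) and "no_compartment" in failed["flags"]

    def test_preset_populations_separate_in_both_metrics(self, optics):
        rows = []
        for preset in ("consolidated", "fragmented"):
            for i, c in enumerate(generate_cell_population(8, preset, seed=61)):
                frame, _ = render_frame([c], optics, seed=i)
                rows.append(morphology_table(frame, [roi_of(c)], 0.11))
        import pandas as pd

        table = pd.concat(rows, ignore_index=True)
        med = table.groupby("condition_label")[["vmi_um2", "tti_per_um"]].median()
        assert med.loc["consolidated", "vmi_um2"] > med.loc["fragmented", "vmi_um2"]
        assert med.loc["consolidated", "tti_per_um"] < med.loc["fragmented", "tti_per_um"]

    def test_ln_vmi_ordering_matches_vmi_ordering(self, optics):
        cells = generate_cell_population(6, "fragmented", seed=71)
        rows = []
        for i, c in enumerate(cells):
            frame, _ = render_frame([c], optics, seed=i)
            rows.append(morphology_table(frame, [roi_of(c)], 0.11))
        import pandas as pd

        t = pd.concat(rows, ignore_index=True).dropna(subset=["vmi_um2"])
        assert (t.sort_values("vmi_um2").cell_id == t.sort_values("ln_vmi").cell_id).all()
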
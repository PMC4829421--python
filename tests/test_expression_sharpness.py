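"""Per-cell quantification and boundary-sharpness index."""

import numpy as np
import pandas as pd
import pytest

from ranoise import expression_sharpness as es


def stack_from(intensity, labels, **kw):
    return es.LabeledStack(
        intensity=np.asarray(intensity), labels=np.asarray(labels, dtype=np.int32), **kw
    )


class TestQuantifyCells:
    def test_uniform_cell_total_is_count_times_value(self):
        labels = np.zeros((1, 10, 10), dtype=np.int32)
        labels[0, 2:7, 2:7] = 1          # 25 voxels
        intensity = np.where(labels > 0, 10, 0).astype(np.uint16)
        table = es.quantify_cells(stack_from(intensity, labels))
        assert table.loc[0, "total"] == 250
        assert table.loc[0, "n_voxels"] == 25

    def test_typical_cell_total_fits_reported_regime(self):
        # 85-pixel cell at mean per-pixel signal 2235 -> total 189,975
        labels = np.zeros((1, 12, 12), dtype=np.int32)
        flat = labels[0].ravel()
        flat[:85] = 1
        intensity = np.where(labels > 0, 2235, 0).astype(np.uint16)
        table = es.quantify_cells(stack_from(intensity, labels))
        assert table.loc[0, "total"] == 85 * 2235 == 189_975
        assert intensity.max() < 4096

    def test_totals_additive_under_label_split(self, rng):
        labels = np.zeros((2, 8, 8), dtype=np.int32)
        labels[:, 1:7, 1:7] = 1
        intensity = rng.integers(0, 4000, labels.shape).astype(np.uint16)
        whole = es.quantify_cells(stack_from(intensity, labels))
        halves = labels.copy()
        halves[:, :, 4:] *= 2            # split cell 1 into labels 1 and 2
        split = es.quantify_cells(stack_from(intensity, halves))
        assert split["total"].sum() == pytest.approx(whole["total"].sum())

    def test_computed_in_3d_not_per_projection(self, rng):
        labels = np.zeros((3, 4, 4), dtype=np.int32)
        labels[:, 1:3, 1:3] = 1
        intensity = rng.integers(0, 100, labels.shape).astype(np.uint16)
        table = es.quantify_cells(stack_from(intensity, labels))
        assert table.loc[0, "total"] == intensity[labels == 1].sum()
        assert table.loc[0, "n_voxels"] == 12

    def test_no_labels_rejected(self):
        z = np.zeros((1, 4, 4), dtype=np.int32)
        with pytest.raises(ValueError):
            es.quantify_cells(stack_from(z.astype(np.uint16), z))


def rect_mask(ny=20, x0=5, x1=15, nx=25):
    m = np.zeros((ny, nx), dtype=bool)
    m[:, x0:x1] = True
    return m


class TestTraceBoundary:
    def test_straight_edge_has_equal_lengths(self):
        tr = es.trace_boundary(rect_mask(), side="posterior")
        assert tr.d_xy == pytest.approx(tr.d_sharp)

    def test_coarse_staircase_approaches_sqrt2(self):
        # equal lateral and axial extent, steps of 8 px
        ny, step = 64, 8
        m = np.zeros((ny, 80), dtype=bool)
        for y in range(ny):
            m[y, : 10 + step * (y // step) + 1] = True
        tr = es.trace_boundary(m, side="posterior")
        assert tr.d_xy / tr.d_sharp == pytest.approx(np.sqrt(2.0), rel=0.08)

    def test_side_flag_selects_facing_edge(self):
        m = np.zeros((10, 30), dtype=bool)
        for y in range(10):
            m[y, 5 : 20 + 3 * (y % 2)] = True   # jagged posterior, flat anterior
        ant = es.trace_boundary(m, side="anterior")
        post = es.trace_boundary(m, side="posterior")
        assert ant.d_xy == pytest.approx(ant.d_sharp)
        assert post.d_xy > post.d_sharp * 1.05

    def test_pixel_size_scales_lengths(self):
        tr1 = es.trace_boundary(rect_mask(), pixel_size=1.0)
        tr2 = es.trace_boundary(rect_mask(), pixel_size=0.5)
        assert tr2.d_xy == pytest.approx(0.5 * tr1.d_xy)

    def test_matches_brute_force_polyline_oracle(self, rng):
        # random blob: dilated union of seed points
        from scipy import ndimage

        m = np.zeros((40, 40), dtype=bool)
        ys, xs = rng.integers(5, 35, 8), rng.integers(5, 35, 8)
        m[ys, xs] = True
        m = ndimage.binary_dilation(m, iterations=6)
        lab, n = ndimage.label(m)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
            m = lab == (1 + int(np.argmax(sizes)))
        tr = es.trace_boundary(m, side="posterior")
        # independent re-computation: explicit per-row max-x walk
        pts = [(y, max(np.flatnonzero(m[y]))) for y in range(40) if m[y].any()]
        d = sum(
            np.hypot(pts[i + 1][0] - pts[i][0], pts[i + 1][1] - pts[i][1])
            for i in range(len(pts) - 1)
        )
        assert tr.d_xy == pytest.approx(d, abs=1e-9)

    def test_disconnected_region_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1:3, 1:3] = True
        m[7:9, 7:9] = True
        with pytest.raises(ValueError, match="disconnected"):
            es.trace_boundary(m)

    def test_single_row_region_rejected(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 2:8] = True
        with pytest.raises(ValueError, match="lateral"):
            es.trace_boundary(m)


class TestSharpnessIndex:
    def test_straight_boundary_scores_one(self):
        res = es.sharpness_index([rect_mask() for _ in range(4)])
        assert res.S == pytest.approx(1.0)

    def test_fine_sawtooth_approaches_inverse_sqrt2(self):
        # 45-degree zigzag: every lateral step shifts the edge by one pixel
        ny = 64
        m = np.zeros((ny, 40), dtype=bool)
        for y in range(ny):
            zig = y % 8 if (y // 8) % 2 == 0 else 7 - y % 8
            m[y, : 15 + zig] = True
        res = es.sharpness_index([m] * 3)
        assert res.S == pytest.approx(1 / np.sqrt(2.0), rel=0.05)

    def test_z_thickness_cancels(self):
        masks = [rect_mask(), np.roll(rect_mask(), 2, axis=1)]
        s1 = es.sharpness_index(masks, z_thickness=1.0).S
        s2 = es.sharpness_index(masks, z_thickness=2.0).S
        assert s1 == s2

    def test_pixel_size_invariance(self):
        masks = [rect_mask() for _ in range(3)]
        assert es.sharpness_index(masks, pixel_size=0.3).S == pytest.approx(
            es.sharpness_index(masks, pixel_size=1.0).S
        )

    def test_degenerate_slices_skipped_then_error(self):
        good = rect_mask()
        empty = np.zeros_like(good)
        res = es.sharpness_index([good, empty])
        assert len(res.traces) == 1
        with pytest.raises(ValueError, match="degenerate"):
            es.sharpness_index([empty, empty])

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            es.SharpnessResult(boundary="x", traces=(), S=1.2)
        with pytest.raises(ValueError):
            es.SharpnessResult(boundary="x", traces=(), S=0.0)


class TestRoughnessMonotonicity:
    def test_sharpness_decreases_with_generator_roughness(self):
        from ranoise.synthetic_data import make_rhombomere_stack

        mean_s = []
        for rough in (0.0, 2.0, 5.0):
            vals = []
            for seed in range(4):
                _, truth = make_rhombomere_stack(
                    shape=(3, 96, 96), roughness=rough, config=seed
                )
                mask = truth["stripe_masks"]["r3"]
                vals.append(es.sharpness_index(list(mask), side="posterior").S)
            mean_s.append(np.mean(vals))
        assert mean_s[0] == pytest.approx(1.0, abs=1e-6)
        assert mean_s[0] > mean_s[1] > mean_s[2]


class TestSharpnessVariance:
    def _results(self, s_values):
        return [
            es.SharpnessResult(boundary="r3r4", traces=(), S=s) for s in s_values
        ]

    def test_identical_indices_zero_variance(self):
        out = es.sharpness_variance(
            {"WT": self._results([0.9] * 5), "MO": self._results([0.8] * 5)}
        )
        assert (out.set_index("condition")["var_S"] == 0).all()

    def test_rough_condition_detected_at_n12(self, rng):
        wt = self._results(np.clip(0.9 + 0.01 * rng.standard_normal(12), 0.01, 1.0))
        mo = self._results(np.clip(0.7 + 0.08 * rng.standard_normal(12), 0.01, 1.0))
        out = es.sharpness_variance({"WT": wt, "crabp2a-MO": mo}).set_index("condition")
        assert out.loc["crabp2a-MO", "levene_p_vs_control"] < 0.05

    def test_permuting_condition_labels_destroys_significance(self, rng):
        wt_vals = np.clip(0.9 + 0.01 * rng.standard_normal(12), 0.01, 1.0)
        mo_vals = np.clip(0.7 + 0.08 * rng.standard_normal(12), 0.01, 1.0)
        pooled = np.concatenate([wt_vals, mo_vals])
        rng.shuffle(pooled)
        out = es.sharpness_variance(
            {"WT": self._results(pooled[:12]), "crabp2a-MO": self._results(pooled[12:])}
        ).set_index("condition")
        real = es.sharpness_variance(
            {"WT": self._results(wt_vals), "crabp2a-MO": self._results(mo_vals)}
        ).set_index("condition")
        assert (
            out.loc["crabp2a-MO", "levene_p_vs_control"]
            > real.loc["crabp2a-MO", "levene_p_vs_control"]
        )

    def test_singleton_condition_excluded(self):
        out = es.sharpness_variance(
            {"WT": self._results([0.9, 0.8, 0.85]), "solo": self._results([0.5])}
        )
        assert "solo" not in set(out["condition"])


def test_stripe_masks_from_labels_recovers_two_stripes():
    from ranoise.synthetic_data import make_rhombomere_stack

    stack, truth = make_rhombomere_stack(shape=(2, 80, 80), roughness=1.0, config=5)
    masks = es.stripe_masks_from_labels(stack)
    assert len(masks) == 2
    # recovered stripes overlap the truth stripes in order
    for got, name in zip(masks, ("r3", "r5")):
        want = truth["stripe_masks"][name]
        inter = (got & want).sum()
        assert inter / want.sum() > 0.6


def test_stack_io_round_trip(tmp_path, rng):
    labels = np.zeros((2, 16, 16), dtype=np.int32)
    labels[:, 4:12, 4:12] = 1
    intensity = rng.integers(0, 4000, labels.shape).astype(np.uint16)
    stack = stack_from(intensity, labels, z_thickness=2.0, pixel_size=0.4)
    es.write_labeled_stack(tmp_path / "i.tif", tmp_path / "l.tif", stack)
    back = es.read_labeled_stack(tmp_path / "i.tif", tmp_path / "l.tif",
                                 z_thickness=2.0, pixel_size=0.4)
    assert np.array_equal(back.intensity, intensity)
    assert np.array_equal(back.labels, labels)


def test_labeled_stack_validation():
    good = np.zeros((1, 4, 4))
    with pytest.raises(ValueError, match="12-bit"):
        stack_from(np.full((1, 4, 4), 5000), np.zeros((1, 4, 4), np.int32))
    with pytest.raises(ValueError, match="shape"):
        stack_from(good, np.zeros((2, 4, 4), np.int32))
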
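import numpy as np
import pytest

from pelvimetry import (
    BinaryMask2D,
    BinaryMask3D,
    LabelVolume,
    Polyline,
    measure_all,
    measure_ippl,
    measure_mul,
    measure_muscle_thickness,
    polyline_length,
    prostate_bladder_interface,
    row_centroid_polyline,
)

from oracles import (
    brute_inscribed_thickness,
    brute_max_perpendicular,
)


def column_mask(n_rows, width=1, spacing=(0.63, 0.63), shape=(40, 20),
                start=(5, 8)):
    data = np.zeros(shape, bool)
    data[start[0]:start[0] + n_rows, start[1]:start[1] + width] = True
    return BinaryMask2D(data, spacing)


class TestPolyline:
    def test_vertical_column_centroids(self):
        p = row_centroid_polyline(column_mask(20))
        assert len(p.points) == 20
        steps = np.linalg.norm(np.diff(p.points, axis=0), axis=1)
        np.testing.assert_allclose(steps, 0.63)

    def test_symmetric_widening_leaves_polyline_unchanged(self):
        p1 = row_centroid_polyline(column_mask(20, width=1))
        p3 = row_centroid_polyline(column_mask(20, width=3, start=(5, 7)))
        np.testing.assert_allclose(p1.points, p3.points)

    def test_oblique_staircase_matches_per_row_means(self, rng):
        data = np.zeros((30, 30), bool)
        for r in range(20):
            data[r + 3, r + 2:r + 2 + 3] = True  # 45-degree strip, width 3
        mask = BinaryMask2D(data, (0.5, 0.7))
        p = row_centroid_polyline(mask)
        for point, row in zip(p.points, p.rows):
            cols = np.nonzero(data[row])[0]
            assert point[0] == pytest.approx(row * 0.5)
            assert point[1] == pytest.approx(cols.mean() * 0.7)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            row_centroid_polyline(BinaryMask2D(np.zeros((4, 4), bool),
                                               (1, 1)))

    def test_length_collinear(self):
        p = row_centroid_polyline(column_mask(20))
        assert polyline_length(p) == pytest.approx(19 * 0.63, abs=1e-12)

    def test_length_degenerate_and_right_angle(self):
        assert polyline_length(Polyline([[0.0, 0.0]], [0])) == 0.0
        p = Polyline([[0, 0], [0, 1], [1, 1]], [0, 1, 2])
        assert polyline_length(p) == pytest.approx(2.0)


class TestMeasureMUL:
    def test_straight_column(self):
        res = measure_mul(column_mask(20))
        assert res.length_mm == pytest.approx(19 * 0.63)
        assert res.n_components_used == 1
        assert res.bridge_length_mm == 0.0

    def test_split_column_bridged_recovers_unsplit_length(self):
        mask = column_mask(20)
        mask.data[15:17] = False    # delete rows 10-11 of the 20-row column
        res = measure_mul(mask, bridge="include")
        assert res.n_components_used == 2
        assert sorted(res.component_lengths_mm, reverse=True) == pytest.approx(
            [9 * 0.63, 7 * 0.63])
        assert res.bridge_length_mm == pytest.approx(3 * 0.63)
        assert res.length_mm == pytest.approx(19 * 0.63)

    def test_exclude_policy_drops_exactly_the_bridge(self):
        mask = column_mask(20)
        mask.data[15:17] = False
        inc = measure_mul(mask, bridge="include")
        exc = measure_mul(mask, bridge="exclude")
        assert inc.length_mm - exc.length_mm == pytest.approx(
            inc.bridge_length_mm)
        assert "bridge_excluded" in exc.flags

    def test_result_invariant_length_decomposition(self):
        mask = column_mask(20)
        mask.data[12:14] = False
        res = measure_mul(mask)
        assert res.length_mm == pytest.approx(
            sum(res.component_lengths_mm) + res.bridge_length_mm, abs=1e-9)

    def test_empty_mask_flagged_zero(self):
        res = measure_mul(BinaryMask2D(np.zeros((5, 5), bool), (1, 1)))
        assert res.length_mm == 0.0
        assert res.n_components_used == 0
        assert "empty_mask" in res.flags

    def test_third_component_ignored_and_flagged(self):
        mask = column_mask(20)
        mask.data[15:17] = False
        mask.data[35, 15] = True    # small distant speck
        res = measure_mul(mask)
        assert res.n_components_used == 2
        assert "components_dropped" in res.flags


class TestInterface:
    def _pair(self, gap_rows, diag=False):
        bladder = np.zeros((20, 20), bool)
        prostate = np.zeros((20, 20), bool)
        bladder[2:8, 5:15] = True
        if diag:
            prostate[8, 15] = True   # touches (7, 14) only diagonally
        else:
            prostate[8 + gap_rows:14, 5:15] = True
        sp = (1.0, 1.0)
        return BinaryMask2D(bladder, sp), BinaryMask2D(prostate, sp)

    def test_separated_structures_no_interface(self):
        b, p = self._pair(gap_rows=2)
        assert len(prostate_bladder_interface(b, p)) == 0

    def test_flat_contact_yields_top_row_points(self):
        b, p = self._pair(gap_rows=0)
        pts = prostate_bladder_interface(b, p)
        assert len(pts) == 10
        assert np.all(pts[:, 0] == 8.0)

    def test_diagonal_contact_invisible_to_cross_element(self):
        b, p = self._pair(gap_rows=0, diag=True)
        assert len(prostate_bladder_interface(b, p, connectivity=4)) == 0
        assert len(prostate_bladder_interface(b, p, connectivity=8)) == 1

    def test_shape_mismatch_raises(self):
        b = BinaryMask2D(np.zeros((5, 5), bool), (1, 1))
        p = BinaryMask2D(np.zeros((6, 5), bool), (1, 1))
        with pytest.raises(ValueError):
            prostate_bladder_interface(b, p)


class TestIPPL:
    def test_no_contact_is_zero(self):
        b = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        b.data[2:6, 4:16] = True
        p = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        p.data[10:16, 4:16] = True
        res = measure_ippl(b, p)
        assert res.ippl_mm == 0.0
        assert "no_interface" in res.flags

    def test_flat_interface_nothing_protrudes(self):
        b = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        b.data[2:8, 4:16] = True
        p = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        p.data[8:15, 4:16] = True
        assert measure_ippl(b, p).ippl_mm == 0.0

    @pytest.mark.parametrize("spacing", [(1.0, 1.0), (0.63, 0.63)])
    def test_semicircular_bump_recovers_height(self, spacing):
        sy, sx = spacing
        H = W = int(round(30 / min(spacing)))
        yy, xx = np.meshgrid(np.arange(H) * sy, np.arange(W) * sx,
                             indexing="ij")
        r0 = H // 2
        y_if, x_c, radius = r0 * sy, (W // 2) * sx, 5.0
        bump = ((yy - y_if) ** 2 + (xx - x_c) ** 2 <= radius ** 2) \
            & (yy < y_if)
        band = (yy >= y_if - 10.0) & (yy < y_if) \
            & (np.abs(xx - x_c) <= 12.0)
        bladder = BinaryMask2D(band & ~bump, spacing)
        prostate = BinaryMask2D(
            ((yy >= y_if) & (np.abs(xx - x_c) <= 10.0)
             & (yy <= y_if + 8.0)) | bump, spacing)
        res = measure_ippl(bladder, prostate)
        assert res.ippl_mm == pytest.approx(radius, abs=max(spacing))
        # cross-check against brute-force max perpendicular distance over
        # the bump's rasterized boundary pixels
        oracle = brute_max_perpendicular(
            np.argwhere(bump) * np.array(spacing),
            res.chord_endpoints[0], res.chord_endpoints[1])
        assert res.ippl_mm <= oracle + 1e-9

    def test_chord_connects_outermost_interface_points(self):
        b = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        b.data[2:8, 3:17] = True
        p = BinaryMask2D(np.zeros((20, 20), bool), (1, 1))
        p.data[8:15, 5:15] = True
        res = measure_ippl(b, p)
        chord = res.chord_endpoints
        width = np.linalg.norm(chord[1] - chord[0])
        assert width == pytest.approx(9.0)  # columns 5..14 on row 8


class TestMuscleThickness:
    def _slab3d(self, width_px, spacing, n_rows=40, n_cols=60):
        data = np.zeros((n_rows, n_cols, 3), bool)
        c0 = (n_cols - width_px) // 2
        data[5:35, c0:c0 + width_px, 1] = True
        return BinaryMask3D(data, spacing)

    def test_axis_aligned_slab_isotropic(self):
        mask = self._slab3d(10, (1.0, 1.0, 3.0))
        res = measure_muscle_thickness(mask)
        assert res.thickness_mm == pytest.approx(10.0, abs=1.0)
        assert res.slice_index_of_max == 1
        oracle = brute_inscribed_thickness(mask.data[:, :, 1], (1.0, 1.0))
        assert abs(res.thickness_mm - oracle) <= 2.0

    def test_same_slab_at_half_spacing(self):
        res = measure_muscle_thickness(self._slab3d(10, (0.5, 0.5, 3.0)))
        assert res.thickness_mm == pytest.approx(5.0, abs=0.5)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 60.0])
    def test_rotated_slab_matches_inscribed_disk_oracle(self, angle):
        from pelvimetry.phantoms import _slab_2d
        sp = (0.63, 0.63)
        plane = _slab_2d((90, 90), sp, (28.0, 28.0), angle, 8.0, 30.0)
        data = np.zeros((90, 90, 3), bool)
        data[:, :, 1] = plane
        res = measure_muscle_thickness(BinaryMask3D(data, (*sp, 3.0)))
        oracle = brute_inscribed_thickness(plane, sp)
        assert abs(res.thickness_mm - oracle) <= 2 * 0.63
        assert res.thickness_mm == pytest.approx(8.0, abs=2 * 0.63)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            measure_muscle_thickness(
                BinaryMask3D(np.zeros((4, 4, 4), bool), (1, 1, 1)))


class TestScaleEquivariance:
    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_all_measurements_scale_with_spacing(self, default_case, k):
        cor, sag = default_case.coronal, default_case.sagittal

        def rescale(vol):
            return LabelVolume(vol.voxels, np.diag([*(vol.spacing * k), 1.0]),
                               vol.schema)

        base = {r.name: r.value_mm
                for r in measure_all(cor, sag)}
        scaled = {r.name: r.value_mm
                  for r in measure_all(rescale(cor), rescale(sag))}
        for name, v in base.items():
            assert scaled[name] == pytest.approx(k * v, rel=1e-12), name


class TestMeasureAll:
    def test_phantom_pair_recovers_truth(self, default_case):
        res = {r.name: r.value_mm
               for r in measure_all(default_case.coronal,
                                    default_case.sagittal)}
        t = default_case.truth
        sy = default_case.spec.spacing[0]
        assert res["coronal_mul"] == pytest.approx(t["coronal_mul"],
                                                   abs=2 * sy)
        assert res["sagittal_mul"] == pytest.approx(t["sagittal_mul"],
                                                    abs=2 * sy)
        assert res["ippl"] == pytest.approx(t["ippl"], abs=sy)
        for key in ("lam_thickness", "oim_thickness",
                    "lam_thickness_left", "oim_thickness_right"):
            assert res[key] == pytest.approx(t[key], abs=2 * sy), key

    def test_missing_bladder_degrades_gracefully(self, default_case):
        sag = default_case.sagittal
        vox = sag.voxels.copy()
        vox[vox == sag.schema.labels["bladder"]] = 0
        stripped = LabelVolume(vox, sag.affine, sag.schema)
        res = {r.name: r for r in measure_all(default_case.coronal, stripped)}
        assert np.isnan(res["ippl"].value_mm) and res["ippl"].flags
        assert res["coronal_mul"].value_mm > 0

    def test_all_zero_volumes_all_flagged(self, default_case):
        def blank(vol):
            return LabelVolume(np.zeros_like(vol.voxels), vol.affine,
                               vol.schema)

        results = measure_all(blank(default_case.coronal),
                              blank(default_case.sagittal))
        assert all(r.flags for r in results)

    def test_deterministic(self, default_case):
        r1 = measure_all(default_case.coronal, default_case.sagittal)
        r2 = measure_all(default_case.coronal, default_case.sagittal)
        assert [(a.name, a.value_mm) for a in r1] == \
            [(b.name, b.value_mm) for b in r2]
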
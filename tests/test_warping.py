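"""Affine application, spherical surface warping, volumetric depth warping."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from elecloc import (
    ElectrodeTable,
    RigidTransform,
    SphereReg,
    WarpField,
    apply_affine,
    check_warp_labels,
    snap_to_surface,
    surface_warp,
    volume_warp,
    warp_all,
)
from elecloc.labeling import label_surface


def _identity_reg(pial_fix):
    """Subject == template: the warp must be the identity on snapped points."""
    return SphereReg(
        subj_pial=pial_fix["pial"],
        subj_sphere=pial_fix["sphere"],
        templ_pial=pial_fix["pial"],
        templ_sphere=pial_fix["sphere"],
    )


def _table(coords, device_type="grid", anatomy=None):
    k = len(coords)
    lab = pd.DataFrame(
        {
            "short_id": [f"E{i}" for i in range(k)],
            "long_id": [f"Elec{i}" for i in range(k)],
            "device_type": [device_type] * k
            if isinstance(device_type, str)
            else device_type,
        }
    )
    if anatomy is not None:
        lab["anatomy"] = anatomy
    return ElectrodeTable(np.asarray(coords, dtype=float), lab)


class TestApplyAffine:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        assert np.array_equal(apply_affine(pts, np.eye(4)), pts)

    def test_pure_translation(self):
        m = np.eye(4)
        m[:3, 3] = (1, 2, 3)
        assert np.allclose(apply_affine(np.zeros((1, 3)), m), [[1, 2, 3]])

    def test_inverse_roundtrip(self, rng):
        t = RigidTransform(translation=(5, -2, 7), rotation=(12, -8, 4))
        pts = rng.normal(size=(1000, 3)) * 50
        back = apply_affine(apply_affine(pts, t.matrix), np.linalg.inv(t.matrix))
        assert np.abs(back - pts).max() < 1e-9

    def test_singular_matrix_rejected(self):
        m = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singular"):
            apply_affine(np.zeros((1, 3)), m)


class TestSnapToSurface:
    def test_exact_vertex(self, pial_fix):
        v = pial_fix["pial"].vertices
        idx, dist, flagged = snap_to_surface(v[[7]], pial_fix["pial"])
        assert idx[0] == 7 and dist[0] == 0.0 and not flagged[0]

    def test_oracle_equivalence(self, pial_fix, rng):
        pts = rng.normal(size=(100, 3)) * 45
        idx, _, _ = snap_to_surface(pts, pial_fix["pial"])
        v = pial_fix["pial"].vertices
        expect = [int(np.argmin(np.linalg.norm(v - p, axis=1))) for p in pts]
        assert np.array_equal(idx, expect)

    def test_large_snap_flagged(self, pial_fix):
        # an electrode floating far off the surface (the across-the-fissure
        # failure mode) must be flagged by its snap distance
        far = np.array([[0.0, 0.0, 80.0]])  # ~15+ mm above a 60 mm surface
        _, dist, flagged = snap_to_surface(far, pial_fix["pial"])
        assert dist[0] > 5.0 and flagged[0]


class TestSurfaceWarp:
    def test_identity_on_vertices(self, pial_fix):
        reg = _identity_reg(pial_fix)
        v = pial_fix["pial"].vertices[[3, 100, 400]]
        assert np.array_equal(surface_warp(v, reg), v)

    def test_identity_on_snapped_electrodes(self, pial_fix, rng):
        reg = _identity_reg(pial_fix)
        pts = rng.normal(size=(30, 3)) * 55
        idx, _, _ = snap_to_surface(pts, pial_fix["pial"])
        out = surface_warp(pts, reg)
        assert np.array_equal(out, pial_fix["pial"].vertices[idx])

    def test_known_rotation_correspondence(self, pial_fix):
        """Subject sphere registered into template space by a known rotation:
        each electrode must land on the template vertex whose sphere
        coordinate is nearest R·(its unregistered sphere point)."""
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        unit = pial_fix["sphere"]
        reg = SphereReg(
            subj_pial=pial_fix["pial"],
            subj_sphere=unit @ R.T,   # subject sphere after registration
            templ_pial=pial_fix["pial"],
            templ_sphere=unit,        # template sphere is the reference
        )
        picks = [5, 77, 300]
        elecs = pial_fix["pial"].vertices[picks]
        out = surface_warp(elecs, reg)
        # analytic expectation, built independently per electrode
        for row, i in enumerate(picks):
            j = int(np.argmax(unit @ (R @ unit[i])))
            assert np.allclose(out[row], pial_fix["pial"].vertices[j])

    def test_label_preserved_under_identity(self, pial_fix):
        reg = _identity_reg(pial_fix)
        annot = pial_fix["annot"]
        v = int(np.flatnonzero(annot == "superiortemporal")[10])
        e = pial_fix["pial"].vertices[[v]] + 0.2
        warped = surface_warp(e, reg)
        assert label_surface(warped, pial_fix["pial"], annot)[0] == "superiortemporal"


class TestVolumeWarp:
    def test_zero_field_is_identity(self, rng):
        f = WarpField(np.zeros((8, 8, 8, 3)), np.eye(4))
        pts = rng.uniform(-3, 3, size=(10, 3))  # surface RAS of the 8-voxel grid
        out, flagged = volume_warp(pts, f)
        assert np.array_equal(out, pts) and not flagged.any()

    def test_uniform_field_shifts(self):
        disp = np.zeros((8, 8, 8, 3))
        disp[..., 0] = 2.0
        f = WarpField(disp, np.eye(4))
        out, _ = volume_warp(np.array([[3.0, 3.0, 3.0]]), f)
        assert np.allclose(out, [[5.0, 3.0, 3.0]])

    def test_matches_analytic_field_off_grid(self, warp_fix, rng):
        field, analytic = warp_fix["field"], warp_fix["analytic"]
        pts = rng.uniform(-25, 25, size=(200, 3))
        out, flagged = volume_warp(pts, field)
        assert not flagged.any()
        assert np.abs(out - (pts + analytic(pts))).max() < 0.01

    def test_linear_in_field_amplitude(self, warp_fix, rng):
        field = warp_fix["field"]
        half = WarpField(field.displacement * 0.5, field.affine)
        pts = rng.uniform(-20, 20, size=(50, 3))
        full, _ = volume_warp(pts, field)
        part, _ = volume_warp(pts, half)
        assert np.allclose(part - pts, (full - pts) * 0.5)

    def test_outside_mask_passed_through_flagged(self):
        f = WarpField(np.ones((8, 8, 8, 3)), np.eye(4))
        with pytest.warns(UserWarning, match="outside"):
            out, flagged = volume_warp(np.array([[100.0, 0, 0]]), f)
        assert flagged[0] and np.allclose(out, [[100.0, 0, 0]])


class TestCheckWarpLabels:
    def test_identity_full_agreement(self, pial_fix):
        pial, annot = pial_fix["pial"], pial_fix["annot"]
        elecs = pial.vertices[[10, 200, 600]]
        table = _table(elecs, anatomy=label_surface(elecs, pial, annot))
        rep = check_warp_labels(table, elecs, templ_mesh=pial, templ_annot=annot)
        assert rep.attrs["agreement"] == 1.0
        assert rep["agree"].all()

    def test_misplaced_depth_flagged_first(self, parc_fix):
        c17 = parc_fix.blob_centers_vox[17]
        c18 = parc_fix.blob_centers_vox[18]
        aff = parc_fix.labels.affine
        w17 = c17 @ aff[:3, :3].T + aff[:3, 3]
        w18 = c18 @ aff[:3, :3].T + aff[:3, 3]
        table = _table(
            np.vstack([w17, w17]), device_type=["depth", "depth"],
            anatomy=["Left-Hippocampus", "Left-Hippocampus"],
        )
        warped = np.vstack([w17, w18])  # second electrode mis-warped
        rep = check_warp_labels(table, warped, templ_parc=parc_fix)
        assert rep.attrs["agreement"] == 0.5
        assert not rep.iloc[0]["agree"]  # mismatches listed first
        assert rep.iloc[0]["warped_label"] == "Left-Amygdala"

    def test_agreement_matches_hand_count(self, pial_fix, rng):
        pial, annot = pial_fix["pial"], pial_fix["annot"]
        elecs = pial.vertices[rng.choice(len(pial.vertices), 10, replace=False)]
        native = label_surface(elecs, pial, annot)
        warped = elecs + rng.normal(0, 8, elecs.shape)
        table = _table(elecs, anatomy=native)
        rep = check_warp_labels(table, warped, templ_mesh=pial, templ_annot=annot)
        manual = np.mean(
            [a == b for a, b in zip(native, label_surface(warped, pial, annot))]
        )
        assert rep.attrs["agreement"] == manual

    def test_missing_anatomy_rejected(self, pial_fix):
        table = _table(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="anatomy"):
            check_warp_labels(table, np.zeros((2, 3)), templ_mesh=pial_fix["pial"],
                              templ_annot=pial_fix["annot"])


class TestWarpAll:
    def _mixed_table(self, pial_fix, parc_fix):
        surf = pial_fix["pial"].vertices[[10, 500]]
        c17 = parc_fix.blob_centers_vox[17]
        aff = parc_fix.labels.affine
        w17 = c17 @ aff[:3, :3].T + aff[:3, 3] + 3.0  # clear of field edges
        coords = np.vstack([surf, w17, w17 + 2.0])
        return _table(coords, device_type=["grid", "grid", "depth", "depth"])

    def test_identity_fixtures_identity_output(self, pial_fix, parc_fix):
        table = self._mixed_table(pial_fix, parc_fix)
        reg = _identity_reg(pial_fix)
        field = WarpField(np.zeros(parc_fix.labels.shape + (3,)), parc_fix.labels.affine)
        out, _ = warp_all(table, reg=reg, field=field)
        assert np.allclose(out.warped_coords, table.coords)

    def test_depth_only_subset(self, pial_fix, parc_fix):
        table = self._mixed_table(pial_fix, parc_fix)
        field = WarpField(np.zeros(parc_fix.labels.shape + (3,)), parc_fix.labels.affine)
        out, _ = warp_all(table, field=field, subset="depth")
        assert np.isnan(out.warped_coords[:2]).all()
        assert not np.isnan(out.warped_coords[2:]).any()

    def test_rows_match_single_device_operations(self, pial_fix, parc_fix, warp_fix):
        table = self._mixed_table(pial_fix, parc_fix)
        reg = _identity_reg(pial_fix)
        field = warp_fix["field"]
        out, _ = warp_all(table, reg=reg, field=field)
        assert np.allclose(out.warped_coords[:2], surface_warp(table.coords[:2], reg))
        assert np.allclose(out.warped_coords[2:], volume_warp(table.coords[2:], field)[0])

    def test_drop_list_clears_warped_rows(self, pial_fix, parc_fix):
        table = self._mixed_table(pial_fix, parc_fix)
        reg = _identity_reg(pial_fix)
        field = WarpField(np.zeros(parc_fix.labels.shape + (3,)), parc_fix.labels.affine)
        out, _ = warp_all(table, reg=reg, field=field, drop=["E3"])
        assert np.isnan(out.warped_coords[3]).all()
        assert not np.isnan(out.warped_coords[:3]).any()
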
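"""Mapping electrodes from native space to a template brain.

Surface devices are warped through spherical correspondence: each
electrode is snapped to its nearest subject pial vertex, carried to that
vertex's position on the subject's registered sphere, matched to the
nearest template sphere vertex by great-circle distance, and placed at
that vertex's position on the template pial surface.  Depth electrodes
are displaced by a dense volumetric warp field (the product of a combined
volumetric/surface registration, consumed here as a displacement volume
in mm).  A label-agreement report compares each electrode's native
anatomy with the anatomy at its warped position, the standard check for
mis-warps (e.g. a hippocampal depth landing in cerebellar cortex).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    ElectrodeTable,
    Parcellation,
    TriMesh,
    Volume,
    surface_ras_offset,
    world_to_voxel,
)
from .labeling import label_depth, label_surface, nearest_vertices

__all__ = [
    "SphereReg", "WarpField", "apply_affine", "snap_to_surface",
    "surface_warp", "volume_warp", "check_warp_labels", "warp_all",
]


@dataclass
class SphereReg:
    """Paired spherical registrations of a subject and a template surface.

    ``subj_sphere[i]`` is the unit-sphere position of subject pial vertex
    ``i`` after spherical (sulcal-pattern) registration; likewise for the
    template.  Correspondence between brains is by proximity on the
    sphere.
    """

    subj_pial: TriMesh
    subj_sphere: np.ndarray
    templ_pial: TriMesh
    templ_sphere: np.ndarray

    def __post_init__(self) -> None:
        self.subj_sphere = _unit_rows(np.asarray(self.subj_sphere, dtype=float))
        self.templ_sphere = _unit_rows(np.asarray(self.templ_sphere, dtype=float))
        if len(self.subj_sphere) != self.subj_pial.n_vertices:
            raise ValueError("subject sphere/pial vertex counts differ")
        if len(self.templ_sphere) != self.templ_pial.n_vertices:
            raise ValueError("template sphere/pial vertex counts differ")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(np.abs(n - 1) > 1e-3):
        warnings.warn("sphere coordinates renormalized to unit radius")
    return x / n


@dataclass
class WarpField:
    """Dense native→template displacement (mm) sampled on a voxel grid."""

    displacement: np.ndarray   # (I, J, K, 3) mm
    affine: np.ndarray         # voxel -> world (scanner RAS)
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must be (I, J, K, 3)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.displacement.shape[:3], dtype=bool)
        if not np.all(np.isfinite(self.displacement[self.valid_mask])):
            raise ValueError("non-finite displacement inside valid mask")

    @property
    def volume(self) -> Volume:
        return Volume(self.displacement[..., 0], self.affine)


def apply_affine(coords: np.ndarray, transform) -> np.ndarray:
    """Apply a rigid transform or general 4x4 matrix to K x 3 coordinates.

    Works identically for electrode tables and mesh vertex arrays (the
    talairach.xfm re-orientation use case).
    """
    coords = np.asarray(coords, dtype=float)
    m = transform.matrix if hasattr(transform, "matrix") else np.asarray(transform, dtype=float)
    if m.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise ValueError("singular transform matrix")
    return coords @ m[:3, :3].T + m[:3, 3]


def snap_to_surface(elecs: np.ndarray, mesh: TriMesh, flag_distance_mm: float = 5.0):
    """Nearest pial vertex per electrode, with snap distances for QC.

    Returns ``(indices, distances, flagged)``.  Large snap distances are
    flagged: they mark the wrong-gyrus failure mode where the nearest
    vertex sits across a fissure (e.g. an STG electrode snapping above
    the Sylvian fissure).
    """
    idx, dist = nearest_vertices(elecs, mesh.vertices)
    return idx, dist, dist > flag_distance_mm


def surface_warp(elecs: np.ndarray, reg: SphereReg) -> np.ndarray:
    """Warp surface electrodes to the template pial surface.

    subject pial snap → subject sphere → nearest template sphere vertex
    (great-circle distance, ties to the lowest index) → template pial
    vertex coordinate.  Every output is an exact template vertex.
    """
    elecs = np.asarray(elecs, dtype=float).reshape(-1, 3)
    idx, _, _ = snap_to_surface(elecs, reg.subj_pial)
    s = reg.subj_sphere[idx]                     # K x 3 on unit sphere
    # angular nearest == chordal nearest on the unit sphere; compute via
    # the max inner product, resolving ties to the lowest template index
    dots = s @ reg.templ_sphere.T                # K x M
    j = np.argmax(dots, axis=1)                  # argmax -> first (lowest) on ties
    return reg.templ_pial.vertices[j].copy()


def volume_warp(elecs: np.ndarray, field: WarpField):
    """Displace electrodes by the trilinearly interpolated warp field.

    Input coordinates are surface RAS of the field's native grid; the
    sampled displacement (mm) is added.  Electrodes outside the valid
    mask are flagged and passed through unchanged.  Returns
    ``(warped K x 3, flagged K bool)``.
    """
    from scipy.ndimage import map_coordinates

    elecs = np.asarray(elecs, dtype=float).reshape(-1, 3)
    vol = Volume(field.displacement[..., 0], field.affine)
    scanner = elecs + surface_ras_offset(vol)
    ijk = world_to_voxel(vol, scanner)
    shape = np.asarray(vol.shape)
    inside = np.all((ijk >= 0) & (ijk <= shape - 1), axis=1)
    if inside.any():
        near = np.clip(np.round(ijk), 0, shape - 1).astype(int)
        inside &= field.valid_mask[near[:, 0], near[:, 1], near[:, 2]]
    disp = np.zeros_like(elecs)
    for c in range(3):
        disp[inside, c] = map_coordinates(
            field.displacement[..., c], ijk[inside].T, order=1, mode="nearest"
        )
    flagged = ~inside
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} electrode(s) outside the warp field; passed through"
        )
    return elecs + disp, flagged


def check_warp_labels(
    native_table: ElectrodeTable,
    warped_coords: np.ndarray,
    templ_parc: Parcellation | None = None,
    templ_mesh: TriMesh | None = None,
    templ_annot: np.ndarray | None = None,
    annot_names: dict | None = None,
) -> pd.DataFrame:
    """Native-vs-warped label agreement report.

    Surface devices are re-labeled at their warped position via the
    template annotation; depths via the template parcellation volume.
    The report lists one row per electrode (mismatches first) and carries
    the overall agreement fraction in ``report.attrs['agreement']``.
    """
    if not native_table.has_anatomy:
        raise ValueError("native table has no anatomy column; run labeling first")
    warped_coords = np.asarray(warped_coords, dtype=float).reshape(-1, 3)
    dev = native_table.labels["device_type"].to_numpy()
    warped_label = np.array([""] * len(native_table), dtype=object)
    is_surf = np.isin(dev, ("grid", "strip"))
    if is_surf.any():
        if templ_mesh is None or templ_annot is None:
            raise ValueError("surface devices present but no template mesh/annot given")
        warped_label[is_surf] = label_surface(
            warped_coords[is_surf], templ_mesh, templ_annot, names=annot_names
        )
    if (~is_surf).any():
        if templ_parc is None:
            raise ValueError("depth devices present but no template parcellation given")
        warped_label[~is_surf] = label_depth(warped_coords[~is_surf], templ_parc)
    native_label = native_table.labels["anatomy"].to_numpy(dtype=object)
    agree = native_label == warped_label
    report = pd.DataFrame(
        {
            "short_id": native_table.labels["short_id"],
            "device_type": dev,
            "native_label": native_label,
            "warped_label": warped_label,
            "agree": agree,
        }
    )
    report = pd.concat([report[~agree], report[agree]]).reset_index(drop=True)
    report.attrs["agreement"] = float(agree.mean()) if len(agree) else 1.0
    return report


def warp_all(
    table: ElectrodeTable,
    reg: SphereReg | None = None,
    field: WarpField | None = None,
    templ_parc: Parcellation | None = None,
    templ_annot: np.ndarray | None = None,
    annot_names: dict | None = None,
    subset: str = "all",
    drop: list | None = None,
):
    """Warp a full montage: surface rows via the sphere, depths via the field.

    ``subset`` restricts warping to {"all", "surface", "depth"}; rows
    outside the subset keep NaN in the warped block.  ``drop`` lists
    short_ids whose warped coordinates are discarded (the manual remedy
    for electrodes the QC shows mis-warped).  Returns ``(table_with_
    warped_block, qc_report_or_None)``.
    """
    if subset not in ("all", "surface", "depth"):
        raise ValueError("subset must be all, surface, or depth")
    out = table.copy()
    dev = out.labels["device_type"].to_numpy()
    is_surf = np.isin(dev, ("grid", "strip"))
    warped = np.full_like(out.coords, np.nan)
    if subset in ("all", "surface") and is_surf.any():
        if reg is None:
            raise ValueError("surface warp requested but no sphere registration given")
        warped[is_surf] = surface_warp(out.coords[is_surf], reg)
    if subset in ("all", "depth") and (~is_surf).any():
        if field is None:
            raise ValueError("depth warp requested but no warp field given")
        warped[~is_surf], _ = volume_warp(out.coords[~is_surf], field)
    if drop:
        mask = out.labels["short_id"].isin(drop).to_numpy()
        warped[mask] = np.nan
    out.warped_coords = warped
    report = None
    if out.has_anatomy and subset == "all":
        done = ~np.isnan(warped).any(axis=1)
        if done.all():
            report = check_warp_labels(
                out, warped, templ_parc=templ_parc,
                templ_mesh=None if reg is None else reg.templ_pial,
                templ_annot=templ_annot, annot_names=annot_names,
            )
    return out, report
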
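"""Subject-directory orchestration: stage dispatch, logging, and QC renders.

A subject directory follows the conventional layout::

    <root>/<subj>/
        acpc/                     original scans
        CT/                       CT.nii and the registered rCT.nii
        elecs/                    electrode tables (montage order)
            individual_elecs/     per-device coordinate files
        Meshes/                   *_trivert.mat surface meshes
            subcortical/
        mri/                      T1.nii, parcellation volumes
            transforms/           plain-text affines, warp fields
        logs/                     JSON-lines stage log

Stages run in the standard order prep → fixtures (synthetic inputs) /
register → interp-grid → project → elecs-all → label → subcort → warp →
qc; each stage checks that its upstream outputs exist and appends a log
record (stage, input hashes, parameters, outputs) sufficient to re-run it
identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, fixtures, grid_geometry, labeling, registration, subcort, warping
from .core_io import (
    ElectrodeTable,
    Parcellation,
    RigidTransform,
    Volume,
    read_electrode_table,
    read_trivert,
    read_volume,
    read_xfm,
    surface_ras_offset,
    world_to_voxel,
    write_electrode_table,
    write_trivert,
    write_volume,
    write_xfm,
)

__all__ = ["SubjectDir", "prep_subject", "run_stage", "qc_render", "refine_coordinate",
           "PipelineError", "STAGE_ORDER"]

HEMS = ("lh", "rh", "stereo")

SUBDIRS = [
    "acpc", "CT", "elecs", "elecs/individual_elecs",
    "Meshes", "Meshes/subcortical", "mri", "mri/transforms", "logs",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class SubjectDir:
    root: Path
    subj: str

    @property
    def path(self) -> Path:
        return Path(self.root) / self.subj

    def file(self, rel: str) -> Path:
        return self.path / rel

    @property
    def config(self) -> dict:
        with open(self.file("config.json")) as f:
            return json.load(f)

    @property
    def hem(self) -> str:
        return self.config["hem"]


def prep_subject(root, subj_id: str, hem: str, zero_indexed: bool = True) -> SubjectDir:
    """Create the subject directory skeleton and persist the config.

    Idempotent: a second run changes nothing.  ``hem`` must be 'lh' or
    'rh' for surface implants, or 'stereo' for a bilateral depth-only
    case.
    """
    if hem not in HEMS:
        raise ValueError(f"hem must be one of {HEMS!r}, got {hem!r}")
    sd = SubjectDir(Path(root), subj_id)
    for d in SUBDIRS:
        sd.file(d).mkdir(parents=True, exist_ok=True)
    cfg_path = sd.file("config.json")
    cfg = {"subj": subj_id, "hem": hem, "zero_indexed": zero_indexed}
    if not cfg_path.exists() or json.loads(cfg_path.read_text()) != cfg:
        cfg_path.write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")
    return sd


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(sd: SubjectDir, record: dict) -> None:
    record = dict(record, time=time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(sd.file("logs/pipeline.jsonl"), "a") as f:
        f.write(json.dumps(record, default=str) + "\n")


# ---------------------------------------------------------------------------
# stage implementations (each takes (sd, params) and returns output paths)

def _stage_fixtures(sd: SubjectDir, p: dict) -> list:
    """Write a full synthetic subject: scans, meshes, corners, warp resources."""
    seed = int(p.get("seed", 0))
    hem = sd.hem if sd.hem != "stereo" else "lh"
    ph = fixtures.make_head_phantom(fixtures.PhantomSpec(seed=seed))
    write_volume(ph["t1"], sd.file("mri/T1.nii"))
    write_volume(ph["ct"], sd.file("CT/CT.nii"))
    np.savetxt(sd.file("CT/true_elecs.txt"), ph["true_elecs"])

    pf = fixtures.make_pial_fixture(seed=seed)
    write_trivert(pf["pial"], sd.file(f"Meshes/{hem}_pial_trivert.mat"))
    np.savez(sd.file(f"Meshes/{hem}_sphere.npz"), sphere=pf["sphere"])
    pd.DataFrame(
        {"vertex_id": np.arange(len(pf["annot"])), "label_id": pf["sector_ids"]}
    ).to_csv(sd.file(f"Meshes/{hem}_annot.csv"), index=False)
    pd.DataFrame(
        [
            {"id": k, "name": v["name"], "r": v["color"][0], "g": v["color"][1], "b": v["color"][2]}
            for k, v in pf["lut"].items()
        ]
    ).to_csv(sd.file(f"Meshes/{hem}_annot_lut.csv"), index=False)

    parc = fixtures.make_parcellation_fixture(seed=seed)
    write_volume(parc.labels, sd.file("mri/aparc+aseg.nii"))

    wf = fixtures.make_warp_fixture(shape=parc.labels.shape, seed=seed)
    import nibabel as nib

    nib.save(
        nib.Nifti1Image(wf["field"].displacement.astype(np.float32), wf["field"].affine),
        sd.file("mri/transforms/cvs_warp_field.nii"),
    )
    # identity template: subject resources double as the template's
    write_trivert(pf["pial"], sd.file("Meshes/template_pial_trivert.mat"))
    np.savez(sd.file("Meshes/template_sphere.npz"), sphere=pf["sphere"])
    write_volume(parc.labels, sd.file("mri/template_aseg.nii"))

    # grid corners: a small square patch facing +x, pushed inside the pial
    # surface to emulate brain shift (projection will recover the surface)
    half = 12.0
    r_in = 0.75 * 60.0
    corners = np.array(
        [[r_in, -half, half], [r_in, half, half], [r_in, -half, -half], [r_in, half, -half]]
    )
    from scipy.io import savemat

    savemat(sd.file("elecs/individual_elecs/hd_grid_corners.mat"), {"elecmatrix": corners})
    # a 4-contact depth trajectory through the hippocampus blob
    aff = parc.labels.affine
    c17 = np.asarray(parc.blob_centers_vox[17])
    center_w = c17 @ aff[:3, :3].T + aff[:3, 3]
    depth = grid_geometry.interp_line(
        np.vstack([center_w - (0, 4.0, 0), center_w + (0, 4.0, 0)]), 4
    )
    savemat(sd.file("elecs/individual_elecs/hippocampal_depth.mat"), {"elecmatrix": depth})
    montage = [
        {"name": "G", "file": "hd_grid.mat", "device_type": "grid",
         "long_id_template": "LGridElectrode{n}"},
        {"name": "HD", "file": "hippocampal_depth.mat", "device_type": "depth",
         "long_id_template": "LHippocampalDepth{n}"},
    ]
    sd.file("elecs/montage.json").write_text(json.dumps(montage, indent=1))
    return ["mri/T1.nii", "CT/CT.nii"]


def _stage_register(sd: SubjectDir, p: dict) -> list:
    fixed = read_volume(sd.file("mri/T1.nii"))
    moving = read_volume(sd.file("CT/CT.nii"))
    opts = registration.RegOptions(
        n_bins=int(p.get("bins", 32)),
        hist_sigma_bins=float(p.get("fwhm", 1.0)),
        interpolation=p.get("interp", "trilinear"),
        seed=int(p.get("seed", 0)),
    )
    init = None
    if "init" in p:
        init = RigidTransform.from_matrix(read_xfm(sd.file(p["init"])))
    t = registration.register_rigid(fixed, moving, init=init, opts=opts)
    rct = registration.resample(moving, t, like=fixed)
    write_volume(rct, sd.file("CT/rCT.nii"))
    write_xfm(t.matrix, sd.file("mri/transforms/ct2t1.xfm"))
    return ["CT/rCT.nii", "mri/transforms/ct2t1.xfm"]


def _stage_interp_grid(sd: SubjectDir, p: dict) -> list:
    base = p.get("grid_basename", "hd_grid")
    nrows, ncols = int(p.get("nrows", 16)), int(p.get("ncols", 16))
    from scipy.io import loadmat, savemat

    corners = loadmat(sd.file(f"elecs/individual_elecs/{base}_corners.mat"))["elecmatrix"]
    grid = grid_geometry.interp_grid(corners, nrows, ncols)
    savemat(
        sd.file(f"elecs/individual_elecs/{base}_orig.mat"),
        {"elecmatrix": grid, "nrows": nrows, "ncols": ncols},
    )
    return [f"elecs/individual_elecs/{base}_orig.mat"]


def _stage_project(sd: SubjectDir, p: dict) -> list:
    base = p.get("grid_basename", "hd_grid")
    hem = sd.hem if sd.hem != "stereo" else "lh"
    from scipy.io import loadmat, savemat

    d = loadmat(sd.file(f"elecs/individual_elecs/{base}_orig.mat"))
    elecs = d["elecmatrix"]
    nrows, ncols = int(np.ravel(d["nrows"])[0]), int(np.ravel(d["ncols"])[0])
    pial = read_trivert(sd.file(f"Meshes/{hem}_pial_trivert.mat"))
    kind = {"hull": "convex_hull", "dural": "smoothed_hull", "OFC": "ofc_submesh"}[
        p.get("surf_type", "dural")
    ]
    surf = grid_geometry.dural_surface(pial, kind=kind,
                                       smoothing_iters=int(p.get("smoothing_iters", 30)))
    frame = grid_geometry.grid_frame(
        elecs[[0, ncols - 1, (nrows - 1) * ncols, nrows * ncols - 1]],
        nrows, ncols, orient_away_from=pial.vertices.mean(axis=0),
    )
    res = grid_geometry.project_electrodes(elecs, surf, frame.mean_normal)
    savemat(sd.file(f"elecs/individual_elecs/{base}.mat"),
            {"elecmatrix": res.coords, "missed": res.missed.astype(int)})
    return [f"elecs/individual_elecs/{base}.mat"]


def _stage_elecs_all(sd: SubjectDir, p: dict) -> list:
    from scipy.io import loadmat

    montage = json.loads(sd.file("elecs/montage.json").read_text())
    devices, coords = [], {}
    for m in montage:
        c = loadmat(sd.file(f"elecs/individual_elecs/{m['file']}"))["elecmatrix"]
        coords[m["name"]] = c
        devices.append(
            labeling.DeviceSpec(
                name=m["name"], device_type=m["device_type"], n_channels=len(c),
                short_id_prefix=m.get("short_id_prefix"),
                long_id_template=m.get("long_id_template"),
            )
        )
    zi = bool(sd.config.get("zero_indexed", True))
    table = labeling.make_elecs_all(labeling.MontageSpec(devices, zero_indexed=zi), coords)
    write_electrode_table(table, sd.file("elecs/elecs_all.mat"))
    return ["elecs/elecs_all.mat"]


def _load_annot(sd: SubjectDir, hem: str):
    annot = pd.read_csv(sd.file(f"Meshes/{hem}_annot.csv"))
    lut = pd.read_csv(sd.file(f"Meshes/{hem}_annot_lut.csv"))
    names = {int(r.id): str(r.name) for r in lut.itertuples()}
    ids = annot.sort_values("vertex_id")["label_id"].to_numpy()
    return ids, names, lut


def _load_parc(sd: SubjectDir, rel: str) -> Parcellation:
    vol = read_volume(sd.file(rel))
    vol = Volume(np.asarray(vol.data).astype(np.int32), vol.affine, vol.frame)
    lut = subcort.default_structures().lut()
    present = set(np.unique(vol.data).tolist()) - {0}
    for pid in present - set(lut):
        lut[pid] = {"name": f"label-{pid}", "color": (128, 128, 128)}
    return Parcellation(vol, lut)


def _stage_label(sd: SubjectDir, p: dict) -> list:
    hem = sd.hem if sd.hem != "stereo" else "lh"
    table = read_electrode_table(sd.file("elecs/elecs_all.mat"))
    pial = read_trivert(sd.file(f"Meshes/{hem}_pial_trivert.mat"))
    ids, names, _ = _load_annot(sd, hem)
    parc = _load_parc(sd, "mri/aparc+aseg.nii")
    dev = table.labels["device_type"].to_numpy()
    anatomy = np.empty(len(table), dtype=object)
    is_surf = np.isin(dev, ("grid", "strip"))
    if is_surf.any():
        anatomy[is_surf] = labeling.label_surface(table.coords[is_surf], pial, ids, names=names)
    if (~is_surf).any():
        anatomy[~is_surf] = labeling.label_depth(table.coords[~is_surf], parc)
    table.labels["anatomy"] = anatomy
    write_electrode_table(table, sd.file("elecs/elecs_all.mat"))
    return ["elecs/elecs_all.mat"]


def _stage_subcort(sd: SubjectDir, p: dict) -> list:
    parc = _load_parc(sd, "mri/aparc+aseg.nii")
    subcort.get_subcort(parc, out_dir=sd.file("Meshes/subcortical"))
    return ["Meshes/subcortical/structures.csv"]


def _stage_warp(sd: SubjectDir, p: dict) -> list:
    hem = sd.hem if sd.hem != "stereo" else "lh"
    table = read_electrode_table(sd.file("elecs/elecs_all.mat"))
    subj_pial = read_trivert(sd.file(f"Meshes/{hem}_pial_trivert.mat"))
    templ_pial = read_trivert(sd.file("Meshes/template_pial_trivert.mat"))
    with np.load(sd.file(f"Meshes/{hem}_sphere.npz")) as f:
        subj_sphere = f["sphere"]
    with np.load(sd.file("Meshes/template_sphere.npz")) as f:
        templ_sphere = f["sphere"]
    reg = warping.SphereReg(subj_pial, subj_sphere, templ_pial, templ_sphere)
    disp, aff = core_io.read_displacement_field(sd.file("mri/transforms/cvs_warp_field.nii"))
    field = warping.WarpField(disp, aff)
    templ_parc = _load_parc(sd, "mri/template_aseg.nii")
    ids, names, _ = _load_annot(sd, hem)
    out, report = warping.warp_all(
        table, reg=reg, field=field, templ_parc=templ_parc,
        templ_annot=ids, annot_names=names,
        subset=p.get("subset", "all"), drop=p.get("drop"),
    )
    write_electrode_table(out, sd.file("elecs/elecs_all_warped.mat"))
    outputs = ["elecs/elecs_all_warped.mat"]
    if report is not None:
        report.to_csv(sd.file("elecs/warp_qc.csv"), index=False)
        outputs.append("elecs/warp_qc.csv")
    return outputs


def _stage_qc(sd: SubjectDir, p: dict) -> list:
    return qc_render(sd, p.get("what", "recon_anatomy"))


STAGES = {
    "fixtures": (_stage_fixtures, []),
    "register": (_stage_register, [("mri/T1.nii", "fixtures"), ("CT/CT.nii", "fixtures")]),
    "interp-grid": (
        _stage_interp_grid,
        [("elecs/individual_elecs/hd_grid_corners.mat", "fixtures")],
    ),
    "project": (
        _stage_project,
        [("elecs/individual_elecs/hd_grid_orig.mat", "interp-grid")],
    ),
    "elecs-all": (_stage_elecs_all, [("elecs/montage.json", "fixtures")]),
    "label": (
        _stage_label,
        [("elecs/elecs_all.mat", "elecs-all"), ("mri/aparc+aseg.nii", "fixtures")],
    ),
    "subcort": (_stage_subcort, [("mri/aparc+aseg.nii", "fixtures")]),
    "warp": (
        _stage_warp,
        [("elecs/elecs_all.mat", "elecs-all"),
         ("mri/transforms/cvs_warp_field.nii", "fixtures")],
    ),
    "qc": (_stage_qc, [("elecs/elecs_all.mat", "elecs-all")]),
}

STAGE_ORDER = ["fixtures", "register", "interp-grid", "project", "elecs-all",
               "label", "subcort", "warp", "qc"]


def run_stage(stage: str, sd: SubjectDir, overrides: dict | None = None) -> list:
    """Run one pipeline stage; refuses to run if upstream outputs are missing.

    Returns the relative paths of the stage's outputs and appends a log
    record with input hashes and the parameter overrides used.
    """
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; stages: {', '.join(STAGE_ORDER)}")
    func, prereqs = STAGES[stage]
    params = dict(overrides or {})
    hashes = {}
    for rel, producer in prereqs:
        # grid_basename override shifts the expected per-device files
        rel = rel.replace("hd_grid", params.get("grid_basename", "hd_grid"))
        path = sd.file(rel)
        if not path.exists():
            raise PipelineError(
                f"stage {stage!r} requires {rel}, which is produced by stage "
                f"{producer!r}; run that stage first"
            )
        hashes[rel] = _sha256(path)
    outputs = func(sd, params)
    _log(sd, {"stage": stage, "inputs": hashes, "params": params, "outputs": outputs})
    return outputs


# ---------------------------------------------------------------------------
# headless QC

def refine_coordinate(ct: Volume, coord_mm: np.ndarray, radius_mm: float = 3.0) -> np.ndarray:
    """Snap a coordinate (surface RAS mm) to the local CT intensity maximum.

    A headless stand-in for centering crosshairs on an electrode
    artifact: the brightest voxel within ``radius_mm`` of the given
    coordinate wins (ties to the lowest flat index).
    """
    coord = np.asarray(coord_mm, dtype=float)
    scanner = coord + surface_ras_offset(ct)
    ijk = world_to_voxel(ct, scanner)
    vs = ct.voxel_size
    r_vox = np.ceil(radius_mm / vs).astype(int)
    lo = np.maximum(np.round(ijk).astype(int) - r_vox, 0)
    hi = np.minimum(np.round(ijk).astype(int) + r_vox + 1, ct.shape)
    sub = ct.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ii, jj, kk = np.indices(sub.shape)
    cand = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + lo
    world = cand @ ct.affine[:3, :3].T + ct.affine[:3, 3]
    keep = np.linalg.norm(world - scanner, axis=1) <= radius_mm
    cand, world = cand[keep], world[keep]
    vals = ct.data[cand[:, 0], cand[:, 1], cand[:, 2]]
    best = int(np.argmax(vals))
    return world[best] - surface_ras_offset(ct)


def _anatomy_colors(sd: SubjectDir, labels: np.ndarray) -> tuple:
    """Map anatomy names to LUT rgb (0-1 floats); unknowns get gray."""
    hem = sd.hem if sd.hem != "stereo" else "lh"
    colors = {}
    lut_path = sd.file(f"Meshes/{hem}_annot_lut.csv")
    if lut_path.exists():
        for r in pd.read_csv(lut_path).itertuples():
            colors[str(r.name)] = (int(r.r), int(r.g), int(r.b))
    for r in subcort.default_structures().table.itertuples():
        colors.setdefault(str(r.name), (int(r.r), int(r.g), int(r.b)))
    rgb = np.array([colors.get(str(l), (128, 128, 128)) for l in labels], dtype=float)
    return rgb / 255.0, colors


def qc_render(sd: SubjectDir, what: str = "recon_anatomy") -> list:
    """Static QC bundles: PNG images + legend/report CSVs.

    * ``recon_anatomy`` — electrodes colored by anatomy over the pial
      silhouette (three orthogonal projections) + label→color CSV.
    * ``warp_compare`` — native vs warped electrode positions side by side.
    * ``depth_warps`` — one panel per depth electrode: native parcellation
      slice crop vs template crop, crosshair on the electrode.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    hem = sd.hem if sd.hem != "stereo" else "lh"
    table = read_electrode_table(sd.file("elecs/elecs_all.mat"))
    if not table.has_anatomy:
        raise PipelineError("qc_render needs the anatomy column; run the label stage")
    rgb, colors = _anatomy_colors(sd, table.labels["anatomy"].to_numpy())
    outputs = []

    if what == "recon_anatomy":
        pial = read_trivert(sd.file(f"Meshes/{hem}_pial_trivert.mat"))
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        planes = [(1, 2, "sagittal"), (0, 2, "coronal"), (0, 1, "axial")]
        for ax, (i, j, name) in zip(axes, planes):
            ax.scatter(pial.vertices[::7, i], pial.vertices[::7, j], s=0.3,
                       c="lightgray", rasterized=True)
            ax.scatter(table.coords[:, i], table.coords[:, j], s=14, c=rgb,
                       edgecolors="k", linewidths=0.3)
            ax.set_title(name)
            ax.set_aspect("equal")
        fig.suptitle(f"{sd.subj}: electrodes by anatomy")
        out = sd.file(f"elecs/{hem}_recon_anatomy.png")
        fig.savefig(out, dpi=110)
        plt.close(fig)
        legend = pd.DataFrame(
            [{"label": k, "r": v[0], "g": v[1], "b": v[2]} for k, v in sorted(colors.items())]
        )
        legend_path = sd.file("elecs/recon_anatomy_legend.csv")
        legend.to_csv(legend_path, index=False)
        outputs = [str(out.relative_to(sd.path)), "elecs/recon_anatomy_legend.csv"]

    elif what == "warp_compare":
        warped = read_electrode_table(sd.file("elecs/elecs_all_warped.mat"))
        if warped.warped_coords is None:
            raise PipelineError("no warped coordinates; run the warp stage")
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, coords, title in zip(
            axes, [warped.coords, warped.warped_coords], ["native", "warped"]
        ):
            ok = ~np.isnan(coords).any(axis=1)
            ax.scatter(coords[ok, 1], coords[ok, 2], s=14, c=rgb[ok],
                       edgecolors="k", linewidths=0.3)
            ax.set_title(title)
            ax.set_aspect("equal")
        out = sd.file("elecs/warp_compare.png")
        fig.savefig(out, dpi=110)
        plt.close(fig)
        outputs = ["elecs/warp_compare.png"]

    elif what == "depth_warps":
        warped = read_electrode_table(sd.file("elecs/elecs_all_warped.mat"))
        parc_n = _load_parc(sd, "mri/aparc+aseg.nii")
        parc_t = _load_parc(sd, "mri/template_aseg.nii")
        depth = np.flatnonzero(warped.labels["device_type"].to_numpy() == "depth")
        if len(depth) == 0:
            raise PipelineError("no depth electrodes to render")
        fig, axes = plt.subplots(len(depth), 2, figsize=(6, 2.6 * len(depth)),
                                 squeeze=False)
        for row, idx in enumerate(depth):
            for col, (coords, parc) in enumerate(
                [(warped.coords, parc_n), (warped.warped_coords, parc_t)]
            ):
                ax = axes[row][col]
                c = coords[idx]
                if np.isnan(c).any():
                    ax.set_axis_off()
                    continue
                vol = parc.labels
                ijk = np.round(
                    world_to_voxel(vol, c + surface_ras_offset(vol))
                ).astype(int)
                ijk = np.clip(ijk, 0, np.asarray(vol.shape) - 1)
                sl = vol.data[:, :, ijk[2]]
                ax.imshow(sl.T, origin="lower", cmap="tab20", interpolation="nearest")
                ax.axhline(ijk[1], color="r", lw=0.6)
                ax.axvline(ijk[0], color="r", lw=0.6)
                ax.set_title(
                    f"{warped.labels['short_id'][idx]} "
                    + ("native" if col == 0 else "warped"), fontsize=8,
                )
        out = sd.file("elecs/depthWarpsQC.png")
        fig.savefig(out, dpi=100)
        plt.close(fig)
        outputs = ["elecs/depthWarpsQC.png"]
    else:
        raise ValueError(f"unknown qc kind {what!r}")
    return outputs
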
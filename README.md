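# elecloc

Localization, anatomical labeling, and atlas warping of intracranial
(ECoG / stereo-EEG) electrodes from a preoperative T1 MRI and a
postoperative CT — as a self-contained Python library and CLI whose every
stage is testable on synthetic phantoms, with no dependency on FreeSurfer
or scanner data.

## Who this is for

Electrophysiology groups recording from subdural grids, strips, and depth
electrodes need, for every subject: the CT (which shows the electrodes)
rigidly aligned to the MRI (which shows the anatomy); coordinates for
every contact, even when high-density grids defeat contact-by-contact
marking; a correction for postoperative brain shift, which leaves grids
apparently buried beneath the preoperative pial surface; an anatomical
label per contact; and a mapping of all contacts to a template brain for
group analyses. `elecloc` implements that chain as composable library
functions plus a subject-directory pipeline.

## What it computes

**Registration.** The CT→MRI rigid transform maximizes normalized mutual
information,

    NMI(A, B) = (H(A) + H(B)) / H(A, B),

with Shannon entropies of a (Gaussian-regularized) joint intensity
histogram. NMI ∈ [1, 2] is invariant to any bijective intensity
relabeling, which is what makes it work across modalities: bone is bright
in CT and dark in T1, yet their statistical dependence peaks when the
skulls align. Optimization is Powell's method over the 6 rigid parameters,
coarse-to-fine over a Gaussian pyramid.

**Grid interpolation.** A high-density grid is reconstructed from its four
marked corners by bilinear interpolation: with u = r/(nrows−1),
v = c/(ncols−1),

    p(r, c) = (1−u)(1−v)·C1 + (1−u)v·C2 + u(1−v)·C3 + uv·C4,

output row-major in channel order (for a 16×16 grid, corner 1 = channel 1,
corner 2 = channel 16, corner 3 = channel 241, corner 4 = channel 256).

**Brain-shift correction.** Each subdural electrode is projected along the
mean of the grid's four corner normals onto a smoothed dural envelope —
the convex hull of the pial mesh, subdivided to ≤3 mm edges and Taubin
(shrinkage-corrected Laplacian) smoothed. Ray–mesh intersection is
Möller–Trumbore, first hit; misses fall back to the nearest surface point
and are flagged.

**Labeling.** Surface devices take the annotation of their Euclidean-
nearest pial vertex; depth electrodes take the lookup-table name of the
parcellation voxel containing them (hippocampus = id 17 in the standard
segmentation LUT).

**Warping.** Surface electrodes map to the template through spherical
correspondence (snap to nearest subject pial vertex → paired sphere
position → nearest template sphere vertex by great-circle distance →
template pial vertex); depth electrodes are displaced by a dense
volumetric warp field. A label-agreement report compares native and
warped anatomy per electrode, the standard check for mis-warps.

**Subcortical meshes.** Marching cubes at iso-level 0.5 over per-structure
binary masks of the segmentation volume, for the canonical 23 subcortical
structures (bilateral accumbens, amygdala, caudate, lateral and inferior
lateral ventricles, pallidum, hippocampus, putamen, thalamus, ventral
diencephalon; midline brain stem, third and fourth ventricles).

## Worked example

```python
import numpy as np
from elecloc import (RegOptions, register_rigid, interp_grid,
                     dural_surface, project_electrodes)
from elecloc.fixtures import (PhantomSpec, make_head_phantom,
                              make_pial_fixture)

phantom = make_head_phantom(PhantomSpec(seed=1))   # T1 + displaced CT
t = register_rigid(phantom["t1"], phantom["ct"], opts=RegOptions(seed=1))
print("recovered translation (mm):", np.round(t.translation, 3))
print("recovered rotation (deg): ", np.round(t.rotation, 3))

corners = np.array([[0., 0, 0], [0, 60, 0], [60, 0, 0], [60, 60, 0]])
grid = interp_grid(corners, 16, 16)                # 256-channel grid

pial = make_pial_fixture(seed=1)                   # bumpy-sphere cortex
surf = dural_surface(pial["pial"], kind="smoothed_hull")
buried = grid * 0.4 + (30, -12, -12)               # grid buried by brain shift
res = project_electrodes(buried, surf, np.array([1.0, 0, 0]))
print("projected displacement (mm): mean %.1f, max %.1f, misses %d"
      % (res.displacement.mean(), res.displacement.max(), res.missed.sum()))
```

prints

```
recovered translation (mm): [ 4.012 -2.99   2.004]
recovered rotation (deg):  [ 3.081 -2.     1.038]
projected displacement (mm): mean 13.2, max 25.8, misses 2
```

The phantom CT was displaced by exactly (4, −3, 2) mm and (3°, −2°, 1°),
so the registration errors here are ≲0.08° and ≲0.02 mm. The projection
moves the deliberately buried grid outward onto the dural envelope; the
two flagged electrodes sat outside the hull with rays pointing away and
were placed at their nearest surface point instead.

The same stages run from the shell on a subject directory:

```sh
elecloc prep --root subjects --subj test_subj --hem lh
elecloc run fixtures --root subjects --subj test_subj --set seed=1
elecloc run register --root subjects --subj test_subj
elecloc run interp-grid --root subjects --subj test_subj
elecloc run project --root subjects --subj test_subj
elecloc run elecs-all --root subjects --subj test_subj
elecloc run label --root subjects --subj test_subj
elecloc run warp --root subjects --subj test_subj
elecloc run qc --root subjects --subj test_subj
```

Stage outputs land in the conventional locations (`CT/rCT.nii`,
`elecs/individual_elecs/hd_grid_orig.mat`, `elecs/elecs_all.mat`,
`Meshes/subcortical/…`), and every run appends a JSON-lines record with
input hashes and parameters to `logs/pipeline.jsonl`.

## Layout

```
src/elecloc/core_io.py        domain types, NIfTI/trivert/electrode-table/xfm I/O
src/elecloc/registration.py   NMI joint histogram, Powell pyramid registration, MIP
src/elecloc/grid_geometry.py  grid interpolation, dural surfaces, ray projection
src/elecloc/labeling.py       nearest-vertex / parcellation labeling, montage tables
src/elecloc/warping.py        affine, spherical and volumetric warps, warp QC
src/elecloc/subcort.py        marching-cubes structure meshes + LUT
src/elecloc/fixtures.py       deterministic synthetic phantoms and surfaces
src/elecloc/pipeline.py       subject directories, stage runner, headless QC renders
src/elecloc/cli.py            `elecloc` command-line interface
```

See `docs/methods.md` for the numerical choices, parameter defaults, and
what the synthetic fixtures do and do not emulate.
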
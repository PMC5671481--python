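"""Deterministic synthetic data emulating the pipeline's imaging inputs.

Every generator is a pure function of its spec and seed (counter-based
Philox RNG), so repeated calls are byte-identical across platforms.  The
generators stand in for: a preoperative T1 and displaced postoperative CT
(head phantom with skull shell and bright electrode artifacts), a pial
surface with paired spherical registration and a sector annotation, a
subcortical parcellation volume with one ellipsoidal blob per structure,
and a smooth volumetric warp field with its closed form available for
oracle evaluation.

What the phantoms emulate and what they do not: geometry, modality
contrast (bone bright in CT / dark in T1), electrode bloom, additive
noise, and a ground-truth rigid displacement are present; bias fields,
beam hardening, partial-volume anatomy, and real gyral geometry are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Parcellation, RigidTransform, TriMesh, Volume
from .subcort import StructureSet, default_structures
from .warping import WarpField

__all__ = [
    "PhantomSpec",
    "make_head_phantom",
    "make_pial_fixture",
    "make_parcellation_fixture",
    "make_warp_fixture",
]


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(seed))


def _centered_affine(shape, voxel_mm: float) -> np.ndarray:
    """1-voxel-iso affine whose world origin is the volume center
    (surface RAS offset is then exactly zero)."""
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = -voxel_mm * (np.asarray(shape, float) - 1) / 2
    return aff


# ---------------------------------------------------------------------------
# head phantom

def _default_electrodes() -> np.ndarray:
    # a 2x4 mini-grid just under the left lateral brain surface (a few mm
    # of clearance from the skull keeps CT artifact centroids unbiased)
    y = np.linspace(-18, 18, 4)
    z = np.array([-6.0, 6.0])
    pts = np.array([[0.0, yy, zz] for zz in z for yy in y])
    pts[:, 0] = -27.0
    return pts


@dataclass
class PhantomSpec:
    """Conditions of the synthetic head phantom.

    Electrode radius defaults to half the 1.17 mm contact diameter of
    high-density grids; the default displacement (4, −3, 2) mm and
    (3°, −2°, 1°) is the ground truth the registration suite recovers.
    """

    shape: tuple = (96, 96, 96)
    voxel_mm: float = 1.0
    brain_semiaxes_mm: tuple = (33.0, 44.0, 38.0)
    skull_gap_mm: float = 3.0
    skull_thickness_mm: float = 4.0
    skull_intensity: float = 2000.0
    electrodes_mm: np.ndarray = field(default_factory=_default_electrodes)
    electrode_radius_mm: float = 1.17 / 2
    electrode_intensity: float = 3200.0
    noise_sigma: float = 2.0
    translation_mm: tuple = (4.0, -3.0, 2.0)
    rotation_deg: tuple = (3.0, -2.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.electrodes_mm = np.asarray(self.electrodes_mm, dtype=float).reshape(-1, 3)


def _ellipsoid_r(world: np.ndarray, semiaxes) -> np.ndarray:
    """Normalized ellipsoidal radius (1.0 on the surface)."""
    return np.sqrt(((world / np.asarray(semiaxes)) ** 2).sum(axis=-1))


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def make_head_phantom(spec: PhantomSpec | None = None) -> dict:
    """Synthetic T1 + displaced CT pair with full ground truth.

    Returns ``t1``, ``ct`` (displaced by ``true_transform``),
    ``ct_aligned`` (same anatomy, no displacement — useful for QC and
    artifact-centroid checks), ``true_transform`` (moving→fixed world,
    the transform registration should recover), and ``true_elecs``
    (electrode centers, mm, in the aligned/T1 frame; surface RAS ==
    scanner RAS here because the affine is volume-centered).
    """
    spec = spec or PhantomSpec()
    aff = _centered_affine(spec.shape, spec.voxel_mm)
    ii, jj, kk = np.indices(spec.shape)
    vox = np.stack([ii, jj, kk], axis=-1).astype(float)
    world = vox * spec.voxel_mm + aff[:3, 3]

    a = np.asarray(spec.brain_semiaxes_mm)
    skull_in = a + spec.skull_gap_mm
    skull_out = skull_in + spec.skull_thickness_mm
    fov_half = (np.asarray(spec.shape) - 1) / 2 * spec.voxel_mm
    if np.any(np.abs(spec.electrodes_mm) > fov_half[None, :]):
        raise ValueError("electrodes outside the field of view")
    if np.any(_ellipsoid_r(spec.electrodes_mm, skull_in) > 1.0):
        raise ValueError("electrodes outside brain/skull interior")

    def t1_at(w):
        r_brain = _ellipsoid_r(w, a)
        r_white = _ellipsoid_r(w, a * 0.68)
        r_sk_in = _ellipsoid_r(w, skull_in)
        r_sk_out = _ellipsoid_r(w, skull_out)
        img = np.zeros(w.shape[:-1])
        img += 80.0 * _smoothstep((1.0 - r_brain) / 0.04 + 0.5)   # gray matter shell
        img += 40.0 * _smoothstep((1.0 - r_white) / 0.06 + 0.5)   # white matter core
        shell = _smoothstep((1.0 - r_sk_out) / 0.03 + 0.5) - _smoothstep(
            (1.0 - r_sk_in) / 0.03 + 0.5
        )
        img += 25.0 * shell                                        # skull, dark in T1
        return img

    def ct_at(w):
        r_sk_in = _ellipsoid_r(w, skull_in)
        r_sk_out = _ellipsoid_r(w, skull_out)
        shell = _smoothstep((1.0 - r_sk_out) / 0.03 + 0.5) - _smoothstep(
            (1.0 - r_sk_in) / 0.03 + 0.5
        )
        img = spec.skull_intensity * shell
        img += 50.0 * _smoothstep((1.0 - _ellipsoid_r(w, a)) / 0.04 + 0.5)  # soft tissue
        w_soft = 0.9  # mm of soft shoulder around each contact (CT bloom)
        for e in spec.electrodes_mm:
            d = np.linalg.norm(w - e, axis=-1)
            prof = _smoothstep((spec.electrode_radius_mm + w_soft - d) / w_soft)
            img = np.maximum(img, spec.electrode_intensity * prof)
        return img

    true_t = RigidTransform(
        translation=np.asarray(spec.translation_mm, float),
        rotation=np.asarray(spec.rotation_deg, float),
        center=np.zeros(3),
    )
    rng = _rng(spec.seed)
    t1 = t1_at(world) + rng.normal(0, spec.noise_sigma, spec.shape)
    ct_aligned = ct_at(world) + rng.normal(0, spec.noise_sigma, spec.shape)
    # the displaced CT shows the aligned anatomy at t(x): registration must
    # find t so that sampling the moving CT at t^-1(fixed world) realigns it
    ct_disp = ct_at(true_t.apply(world.reshape(-1, 3)).reshape(world.shape))
    ct_disp = ct_disp + rng.normal(0, spec.noise_sigma, spec.shape)
    return {
        "t1": Volume(t1, aff),
        "ct": Volume(ct_disp, aff),
        "ct_aligned": Volume(ct_aligned, aff),
        "true_transform": true_t,
        "true_elecs": spec.electrodes_mm.copy(),
    }


# ---------------------------------------------------------------------------
# pial surface fixture

_SECTOR_NAMES = [
    "superiortemporal", "precentral", "postcentral", "parstriangularis",
    "caudalmiddlefrontal", "supramarginal", "superiorfrontal", "middletemporal",
]


def _icosphere(n_subdiv: int) -> TriMesh:
    import trimesh as tm

    s = tm.creation.icosphere(subdivisions=n_subdiv, radius=1.0)
    return TriMesh(np.asarray(s.vertices), np.asarray(s.faces))


def make_pial_fixture(
    n_subdiv: int = 3,
    bumpiness: float = 5.0,
    radius: float = 60.0,
    n_sectors: int = 6,
    seed: int = 0,
) -> dict:
    """Deformed-icosphere pial mesh with exact spherical pairing.

    The pial surface is a radius-``radius`` icosphere perturbed radially
    by smooth random bumps and indentations of peak amplitude
    ``bumpiness`` mm (gyri and sulci); the paired sphere coordinates are
    the *unperturbed* unit icosphere vertices, so the spherical
    registration is exact by construction.  The annotation partitions the
    vertices into ``n_sectors`` azimuthal sectors named after gyral
    regions of a coarse cortical atlas.
    """
    if n_subdiv < 2:
        raise ValueError("n_subdiv must be >= 2")
    unit = _icosphere(n_subdiv)
    u = unit.vertices
    rng = _rng(seed)
    bump = np.zeros(len(u))
    if bumpiness > 0:
        n_bumps = 12
        dirs = rng.normal(size=(n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        amps = rng.uniform(-1.0, 1.0, n_bumps)
        widths = rng.uniform(0.08, 0.25, n_bumps)
        for d, amp, w in zip(dirs, amps, widths):
            bump += amp * np.exp(-(1.0 - u @ d) / w)
        peak = np.abs(bump).max()
        if peak > 0:
            bump *= bumpiness / peak
    pial = TriMesh((radius + bump)[:, None] * u, unit.triangles)
    az = np.arctan2(u[:, 1], u[:, 0])  # (-pi, pi]
    sector = np.floor((az + np.pi) / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    names = [_SECTOR_NAMES[i % len(_SECTOR_NAMES)] for i in range(n_sectors)]
    annot = np.array([names[s] for s in sector], dtype=object)
    lut = {
        i + 1: {"name": names[i], "color": tuple(int(c) for c in rng.integers(0, 256, 3))}
        for i in range(n_sectors)
    }
    return {"pial": pial, "sphere": u.copy(), "annot": annot, "sector_ids": sector + 1, "lut": lut}


# ---------------------------------------------------------------------------
# parcellation fixture

def make_parcellation_fixture(
    shape: tuple = (96, 96, 96),
    structures: StructureSet | None = None,
    voxel_mm: float = 1.0,
    seed: int = 0,
) -> Parcellation:
    """One ellipsoidal blob per structure on a deterministic lattice.

    Blob centers sit on a cubic lattice with spacing wide enough that
    blobs can never overlap (overlap is nonetheless checked and is an
    error).  Ids follow the standard segmentation LUT (hippocampus = 17).
    The returned parcellation carries ``blob_centers_vox`` (id → center
    voxel) for oracle checks.
    """
    structures = default_structures() if structures is None else structures
    n = len(structures)
    shape = tuple(shape)
    rng = _rng(seed)
    per_axis = int(np.ceil(n ** (1 / 3))) if n else 1
    spacing = np.asarray(shape) / (per_axis + 0.0001)
    max_semi = spacing.min() / 2 - 1.5
    if max_semi < 2:
        raise ValueError("grid too small for the requested structure count")
    labels = np.zeros(shape, dtype=np.int32)
    ii, jj, kk = np.indices(shape)
    centers = {}
    idx = 0
    order = structures.table.sort_values("id").itertuples()
    for r in order:
        cell = np.array(np.unravel_index(idx, (per_axis,) * 3), dtype=float)
        center = (cell + 0.5) * spacing
        semi = rng.uniform(0.45, 0.95, 3) * max_semi
        blob = (
            ((ii - center[0]) / semi[0]) ** 2
            + ((jj - center[1]) / semi[1]) ** 2
            + ((kk - center[2]) / semi[2]) ** 2
        ) <= 1.0
        if np.any(labels[blob] != 0):
            raise ValueError("blob overlap in parcellation fixture")
        labels[blob] = int(r.id)
        centers[int(r.id)] = center
        idx += 1
    vol = Volume(labels, _centered_affine(shape, voxel_mm))
    parc = Parcellation(vol, structures.lut())
    parc.blob_centers_vox = centers
    return parc


# ---------------------------------------------------------------------------
# warp field fixture

def make_warp_fixture(
    shape: tuple = (64, 64, 64),
    amplitude_mm: float = 3.0,
    voxel_mm: float = 1.0,
    seed: int = 0,
) -> dict:
    """Smooth low-frequency sinusoidal displacement field + closed form.

    The analytic displacement (world mm → mm displacement) is returned
    alongside the sampled field so interpolation can be checked against
    an exact oracle.  Wavelengths are twice the field of view, so the
    field is very smooth at the voxel scale.
    """
    extent = np.asarray(shape) * voxel_mm
    if amplitude_mm >= extent.min() / 10:
        raise ValueError("amplitude too large for the grid extent")
    rng = _rng(seed)
    phases = rng.uniform(0, 2 * np.pi, 3)
    freq = 2 * np.pi / (2 * extent)  # one half-cycle across the volume

    def analytic(world: np.ndarray) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        out = np.empty_like(world)
        for c in range(3):
            out[..., c] = amplitude_mm * np.sin(freq[c] * world[..., (c + 1) % 3] + phases[c])
        return out

    aff = _centered_affine(shape, voxel_mm)
    ii, jj, kk = np.indices(shape)
    world = np.stack([ii, jj, kk], axis=-1) * voxel_mm + aff[:3, 3]
    disp = analytic(world)
    field = WarpField(displacement=disp, affine=aff)
    return {"field": field, "analytic": analytic}
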
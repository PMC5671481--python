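"""Domain types, coordinate conventions, and file I/O.

Coordinate conventions
----------------------
* Voxel indices are 0-based and the affine maps voxel *centers* to world
  coordinates (mm, RAS orientation).
* Two world frames are distinguished: ``scanner_ras`` (the frame of the
  NIfTI affine) and ``surface_ras`` (scanner RAS re-centered on the
  geometric center of the imaged volume, the frame in which surface meshes
  and electrode coordinates live).  :func:`surface_ras_offset` returns the
  translation between them.
* Triangle meshes carry vertices in surface RAS mm with 0-based triangle
  indices, stored on disk in a MAT-dialect container under the keys
  ``vert``/``tri`` (``*_trivert.mat``); npz and HDF5 containers with the
  same keys are accepted on read.
* Electrode tables are stored with keys ``elecmatrix`` (K x 3 coordinates)
  and ``eleclabels`` (short id, long id, device type, and — once labeling
  has run — an anatomy column).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume", "TriMesh", "ElectrodeTable", "RigidTransform", "Parcellation",
    "read_volume", "write_volume", "read_trivert", "write_trivert",
    "read_electrode_table", "write_electrode_table", "read_xfm", "write_xfm",
    "voxel_to_world", "world_to_voxel", "surface_ras_offset",
]

DEVICE_TYPES = ("grid", "strip", "depth")


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Volume:
    """A 3D scalar grid with a voxel→world affine.

    Parameters
    ----------
    data : (I, J, K) ndarray
        Scalar intensities, arbitrary units.
    affine : (4, 4) ndarray
        Voxel→world map; world units mm, RAS orientation, voxel-center
        convention.
    frame : {"scanner_ras", "surface_ras"}
        World frame of the affine.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str = "scanner_ras"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if any(s < 2 for s in self.data.shape):
            raise ValueError("volume needs >= 2 voxels per axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.frame not in ("scanner_ras", "surface_ras"):
            raise ValueError(f"unknown frame {self.frame!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def to_surface_ras(self) -> "Volume":
        """Return a copy whose affine is expressed in surface RAS."""
        if self.frame == "surface_ras":
            return self
        off = surface_ras_offset(self)
        aff = self.affine.copy()
        aff[:3, 3] -= off
        return Volume(self.data, aff, frame="surface_ras")


@dataclass
class TriMesh:
    """Triangle mesh: vertices (surface RAS, mm) and 0-based triangle indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be N x 3")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be M x 3")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("malformed trivert: triangle index out of range")
        if self.triangles.size:
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("degenerate triangle (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def euler_characteristic(self) -> int:
        """V - E + F; equals 2 for a closed genus-0 surface."""
        edges = np.sort(self.triangles[:, [0, 1, 1, 2, 0, 2]].reshape(-1, 2), axis=1)
        n_edges = len(np.unique(edges, axis=0))
        return self.n_vertices - n_edges + len(self.triangles)

    def volume(self) -> float:
        """Enclosed volume via the divergence theorem (signed, absolute value)."""
        v = self.vertices
        t = self.triangles
        a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
        return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


@dataclass
class ElectrodeTable:
    """Electrode coordinates plus per-row device descriptors.

    ``labels`` is a DataFrame with columns ``short_id``, ``long_id``,
    ``device_type`` (grid/strip/depth) and, after anatomical labeling,
    ``anatomy``.  ``coords`` is the K x 3 ``elecmatrix`` in surface RAS mm.
    """

    coords: np.ndarray
    labels: pd.DataFrame
    zero_indexed: bool = True
    warped_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.coords) != len(self.labels):
            raise ValueError("coords and labels row counts differ")
        for col in ("short_id", "long_id", "device_type"):
            if col not in self.labels.columns:
                raise ValueError(f"labels missing required column {col!r}")
        for col in ("short_id", "long_id"):
            if self.labels[col].duplicated().any():
                dupes = self.labels[col][self.labels[col].duplicated()].tolist()
                raise ValueError(f"duplicate {col}: {dupes}")
        bad = set(self.labels["device_type"]) - set(DEVICE_TYPES)
        if bad:
            raise ValueError(f"device_type must be one of {DEVICE_TYPES}, got {sorted(bad)}")
        self.labels = self.labels.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def has_anatomy(self) -> bool:
        return "anatomy" in self.labels.columns

    def copy(self) -> "ElectrodeTable":
        return ElectrodeTable(
            self.coords.copy(),
            self.labels.copy(),
            self.zero_indexed,
            None if self.warped_coords is None else self.warped_coords.copy(),
        )


@dataclass
class RigidTransform:
    """6-DOF rigid world→world map.

    Rotation is parameterized as intrinsic x–y–z Euler angles in degrees,
    applied about ``center`` (mm); translation is in mm.  The 4x4 matrix
    form is derived and kept consistent with the parameters.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        R = Rotation.from_euler("XYZ", self.rotation, degrees=True).as_matrix()
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.translation + self.center - R @ self.center
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, m: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        R = m[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ValueError("matrix is not a proper rotation")
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
        t = m[:3, 3] - c + R @ c
        return cls(translation=t, rotation=angles, center=c)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        m = self.matrix
        return pts @ m[:3, :3].T + m[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), center=self.center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix, center=self.center)


@dataclass
class Parcellation:
    """Integer label volume plus a lookup table id → (name, rgb color).

    ``annot``, when present, holds per-vertex label ids for a companion
    surface mesh (cortical annotation).
    """

    labels: Volume
    lut: dict
    annot: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.issubdtype(self.labels.data.dtype, np.integer):
            raise ValueError("parcellation volume must be integer-valued")
        present = set(np.unique(self.labels.data).tolist()) - {0}
        missing = present - set(self.lut)
        if missing:
            raise ValueError(f"label ids missing from LUT: {sorted(missing)}")

    def name_of(self, label_id: int) -> str:
        if label_id == 0 or label_id not in self.lut:
            return "Unknown"
        return self.lut[label_id]["name"]


# ---------------------------------------------------------------------------
# coordinate helpers

def voxel_to_world(vol: Volume, ijk: np.ndarray) -> np.ndarray:
    """Map (fractional) voxel indices through the affine to world mm."""
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ vol.affine[:3, :3].T + vol.affine[:3, 3]


def world_to_voxel(vol: Volume, xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`voxel_to_world`; fractional indices allowed."""
    xyz = np.asarray(xyz, dtype=float)
    inv = np.linalg.inv(vol.affine)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def surface_ras_offset(vol: Volume) -> np.ndarray:
    """World coordinate of the volume's geometric center.

    Subtracting this offset converts scanner RAS to surface RAS (the
    FreeSurfer c_ras convention: meshes are expressed relative to the
    center of the conformed volume).
    """
    center_ijk = (np.asarray(vol.shape, dtype=float) - 1.0) / 2.0
    return voxel_to_world(vol, center_ijk)


# ---------------------------------------------------------------------------
# volumes

def read_volume(path: os.PathLike | str) -> Volume:
    """Read a NIfTI-1 volume, reoriented so the affine is RAS-positive."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"unreadable volume: {path} does not exist")
    try:
        img = nib.load(path)
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises many types on corrupt input
        raise IOError(f"unreadable volume: {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return Volume(data, affine, frame="scanner_ras")


def write_volume(vol: Volume, path: os.PathLike | str) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, os.fspath(path))


def read_displacement_field(path: os.PathLike | str):
    """Read a 4D NIfTI (3 displacement components, mm) as (data4d, affine)."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 5:  # NIfTI vector convention (i,j,k,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError("displacement field must have 3 components on the 4th axis")
    return data, np.asarray(img.affine, dtype=float)


# ---------------------------------------------------------------------------
# meshes (trivert container)

def write_trivert(mesh: TriMesh, path: os.PathLike | str) -> None:
    """Write a mesh as a ``vert``/``tri`` container (.mat, .npz, or .h5)."""
    path = os.fspath(path)
    vert = np.asarray(mesh.vertices, dtype=np.float64)
    tri = np.asarray(mesh.triangles, dtype=np.int64)
    if path.endswith(".npz"):
        np.savez(path, vert=vert, tri=tri)
    elif path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("vert", data=vert)
            f.create_dataset("tri", data=tri)
    else:
        from scipy.io import savemat

        savemat(path, {"vert": vert, "tri": tri})


def read_trivert(path: os.PathLike | str) -> TriMesh:
    path = os.fspath(path)
    if path.endswith(".npz"):
        with np.load(path) as f:
            vert, tri = f["vert"], f["tri"]
    elif path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            vert, tri = f["vert"][()], f["tri"][()]
    else:
        from scipy.io import loadmat

        d = loadmat(path)
        if "vert" not in d or "tri" not in d:
            raise ValueError(f"malformed trivert: {path} lacks vert/tri keys")
        vert, tri = d["vert"], d["tri"]
    try:
        return TriMesh(vert, tri)
    except ValueError as exc:
        raise ValueError(f"malformed trivert: {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# electrode tables

def write_electrode_table(table: ElectrodeTable, path: os.PathLike | str) -> None:
    """Serialize under keys ``elecmatrix`` / ``eleclabels`` (.mat or .npz)."""
    path = os.fspath(path)
    cols = ["short_id", "long_id", "device_type"]
    if table.has_anatomy:
        cols.append("anatomy")
    lab = table.labels[cols].astype(str).to_numpy(dtype=object)
    payload = {
        "elecmatrix": np.asarray(table.coords, dtype=np.float64),
        "eleclabels": lab,
        "zero_indexed": np.array([int(table.zero_indexed)]),
    }
    if table.warped_coords is not None:
        payload["elecmatrix_warped"] = np.asarray(table.warped_coords, dtype=np.float64)
    if path.endswith(".npz"):
        np.savez(path, **{k: (v if k != "eleclabels" else v.astype("U")) for k, v in payload.items()})
    else:
        from scipy.io import savemat

        savemat(path, payload)


def read_electrode_table(path: os.PathLike | str) -> ElectrodeTable:
    path = os.fspath(path)
    if path.endswith(".npz"):
        with np.load(path, allow_pickle=False) as f:
            d = {k: f[k] for k in f.files}
    else:
        from scipy.io import loadmat

        d = loadmat(path)
    if "elecmatrix" not in d or "eleclabels" not in d:
        raise ValueError(f"malformed electrode table: {path}")
    coords = np.asarray(d["elecmatrix"], dtype=float).reshape(-1, 3)
    raw = np.asarray(d["eleclabels"])
    rows = []
    for r in raw:
        rows.append([_as_str(x) for x in np.ravel(np.asarray(r, dtype=object))][: raw.shape[1]])
    cols = ["short_id", "long_id", "device_type", "anatomy"][: raw.shape[1]]
    labels = pd.DataFrame(rows, columns=cols)
    zero_indexed = True
    if "zero_indexed" in d:
        zero_indexed = bool(np.ravel(d["zero_indexed"])[0])
    warped = None
    if "elecmatrix_warped" in d:
        warped = np.asarray(d["elecmatrix_warped"], dtype=float).reshape(-1, 3)
    return ElectrodeTable(coords, labels, zero_indexed=zero_indexed, warped_coords=warped)


def _as_str(x) -> str:
    while isinstance(x, np.ndarray):
        if x.size == 0:
            return ""
        x = x.ravel()[0] if x.size > 1 or x.ndim else x.item()
    return str(x)


# ---------------------------------------------------------------------------
# plain-text affine (talairach.xfm dialect)

def write_xfm(matrix: np.ndarray, path: os.PathLike | str) -> None:
    """Write a 4x4 affine in the MNI/FreeSurfer linear transform dialect."""
    m = np.asarray(matrix, dtype=float)
    lines = [
        "MNI Transform File",
        "% written by elecloc",
        "",
        "Transform_Type = Linear;",
        "Linear_Transform =",
    ]
    for i in range(3):
        row = " ".join(f"{v:.9f}" for v in m[i])
        lines.append(row + (";" if i == 2 else ""))
    with open(os.fspath(path), "w") as f:
        f.write("\n".join(lines) + "\n")


def read_xfm(path: os.PathLike | str) -> np.ndarray:
    """Parse the plain-text linear transform dialect; returns a 4x4 matrix."""
    with open(os.fspath(path)) as f:
        text = f.read()
    if "Linear_Transform" in text:
        body = text.split("Linear_Transform", 1)[1].split("=", 1)[1]
    else:
        body = text
    nums = []
    for tok in body.replace(";", " ").split():
        try:
            nums.append(float(tok))
        except ValueError:
            continue
    if len(nums) < 12:
        raise ValueError(f"malformed xfm file: {path}")
    m = np.eye(4)
    m[:3, :] = np.asarray(nums[:12]).reshape(3, 4)
    return m
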
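"""Anatomical labeling of electrodes and montage-table assembly.

Surface devices (grids, strips) are labeled by the annotation of their
Euclidean-nearest pial vertex; depth electrodes by the value of the
parcellation voxel containing them.  Labels are copied verbatim from the
annotation names / lookup table — cortical gyral names are lowercase
("superiortemporal"), volumetric structures keep their LUT spelling
("Left-Hippocampus"); no case normalization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import (
    ElectrodeTable,
    Parcellation,
    TriMesh,
    Volume,
    surface_ras_offset,
    world_to_voxel,
)

__all__ = [
    "MontageSpec", "DeviceSpec", "nearest_vertices",
    "label_surface", "label_depth", "make_elecs_all", "edit_labels",
]


def nearest_vertices(points: np.ndarray, vertices: np.ndarray):
    """Euclidean-nearest vertex index per point, ties to the lowest index.

    Returns ``(indices, distances)``.  A k-d tree provides the candidate;
    exact ties (and near-ties within floating-point noise of the squared
    distance) are re-resolved to the lowest vertex index.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    vertices = np.asarray(vertices, dtype=float)
    if len(vertices) == 0:
        raise ValueError("empty mesh")
    tree = cKDTree(vertices)
    dist, idx = tree.query(points, k=1)
    # tie-break: any vertex at the same distance (to 1e-9 mm) with a lower index wins
    for i, (d, j) in enumerate(zip(dist, idx)):
        cands = tree.query_ball_point(points[i], r=d + 1e-9)
        if len(cands) > 1:
            dd = np.linalg.norm(vertices[cands] - points[i], axis=1)
            tied = [c for c, x in zip(cands, dd) if x <= d + 1e-9]
            idx[i] = min(tied)
    return idx, dist


def label_surface(elecs: np.ndarray, mesh: TriMesh, annot: np.ndarray,
                  names: dict | None = None) -> list:
    """Label each electrode with the annotation of its nearest vertex.

    ``annot`` holds one label per mesh vertex — either names directly, or
    integer ids resolved through ``names`` (id → name).
    """
    annot = np.asarray(annot)
    if len(annot) != mesh.n_vertices:
        raise ValueError("annotation length must equal mesh vertex count")
    idx, dist = nearest_vertices(elecs, mesh.vertices)
    out = []
    for i, d in zip(idx, dist):
        lab = annot[i]
        if names is not None:
            lab = names.get(int(lab), "Unknown")
        out.append(str(lab))
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def label_depth(elecs: np.ndarray, parc: Parcellation,
                vol_frame: Volume | None = None) -> list:
    """Label depth electrodes by the parcellation voxel they occupy.

    Electrode coordinates (surface RAS mm) are converted to scanner RAS by
    adding the volume-center offset, mapped to voxel indices, and rounded
    half-away-from-zero to the nearest voxel.  Voxel id 0, an id missing
    from the LUT, or a coordinate outside the volume yields "Unknown".
    """
    vol = vol_frame if vol_frame is not None else parc.labels
    elecs = np.asarray(elecs, dtype=float).reshape(-1, 3)
    scanner = elecs + surface_ras_offset(vol)
    ijk = _round_half_away(world_to_voxel(vol, scanner))
    shape = np.asarray(parc.labels.shape)
    out = []
    for v in ijk:
        if np.any(v < 0) or np.any(v >= shape):
            warnings.warn("electrode outside parcellation volume; labeled Unknown")
            out.append("Unknown")
            continue
        out.append(parc.name_of(int(parc.labels.data[tuple(v)])))
    return out


@dataclass
class DeviceSpec:
    """One device in the recording montage."""

    name: str
    device_type: str              # grid | strip | depth
    n_channels: int
    short_id_prefix: str | None = None    # default: name
    long_id_template: str | None = None   # format string with {n}; default "{name}Electrode{n}"

    def __post_init__(self) -> None:
        if self.short_id_prefix is None:
            self.short_id_prefix = self.name
        if self.long_id_template is None:
            self.long_id_template = self.name + "Electrode{n}"


@dataclass
class MontageSpec:
    """Ordered devices making up the montage; channel ranges are implied
    by the order and are contiguous and disjoint by construction."""

    devices: list
    zero_indexed: bool = True

    def __post_init__(self) -> None:
        if not self.devices:
            raise ValueError("montage spec has no devices")


def make_elecs_all(spec: MontageSpec, device_coords: dict) -> ElectrodeTable:
    """Concatenate per-device coordinates into the montage-ordered table.

    ``device_coords`` maps device name → K x 3 coordinate array.  Short
    ids are ``prefix + channel`` and long ids come from the device's
    template; channel numbering starts at 0 or 1 per the montage's
    ``zero_indexed`` flag.  The anatomy column is absent until labeling.
    """
    coords, rows = [], []
    start = 0 if spec.zero_indexed else 1
    for dev in spec.devices:
        if dev.name not in device_coords:
            raise ValueError(f"missing coordinates for device {dev.name!r}")
        c = np.asarray(device_coords[dev.name], dtype=float).reshape(-1, 3)
        if len(c) != dev.n_channels:
            raise ValueError(
                f"device {dev.name!r}: expected {dev.n_channels} channels, got {len(c)}"
            )
        coords.append(c)
        for ch in range(start, start + dev.n_channels):
            rows.append(
                {
                    "short_id": f"{dev.short_id_prefix}{ch}",
                    "long_id": dev.long_id_template.format(n=ch),
                    "device_type": dev.device_type,
                }
            )
    table = ElectrodeTable(
        np.vstack(coords), pd.DataFrame(rows), zero_indexed=spec.zero_indexed
    )
    return table


def edit_labels(table: ElectrodeTable, revisions: dict) -> ElectrodeTable:
    """Apply manual anatomy corrections: {anatomy name: [electrode indices]}.

    Indices follow the table's ``zero_indexed`` flag.  Only the listed
    rows change; each edit is appended to ``table.provenance`` on the
    returned copy.
    """
    out = table.copy()
    if "anatomy" not in out.labels.columns:
        out.labels["anatomy"] = ""
    prov = list(getattr(table, "provenance", []))
    offset = 0 if table.zero_indexed else 1
    n = len(table)
    for name, indices in revisions.items():
        for i in indices:
            row = i - offset
            if not (0 <= row < n):
                raise IndexError(f"electrode index {i} out of range for table of {n}")
            old = out.labels.at[row, "anatomy"]
            out.labels.at[row, "anatomy"] = name
            prov.append({"row": int(row), "old": str(old), "new": name})
    out.provenance = prov
    return out
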
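"""Surface extraction and printability validation for the phantom compartments.

Each compartment's interface shell is the one-voxel-thick boundary layer
(voxels sharing a vertex, edge or face with the outside, scanned outside-in).
Triangle surfaces are produced by marching cubes at iso-level 0.5 on the
binary compartment mask — padded by one background voxel so the surface
always closes — and exported as binary STL for printing.  Validation checks
the "nonperforated" requirement (watertightness), counts components, and
measures minimum wall separation between compartments on the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume import BACKGROUND

__all__ = [
    "SurfaceMesh",
    "MeshReport",
    "extract_shell",
    "voxels_to_mesh",
    "remove_noise_shells",
    "validate_mesh",
    "write_stl",
    "read_stl",
    "extract_compartment_meshes",
]

_VERTEX_STRUCT = np.ones((3, 3, 3), dtype=bool)  # 26-neighborhood


@dataclass
class SurfaceMesh:
    """Triangle mesh in world millimetres for one compartment."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    compartment: int = -1

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        if self.faces.size and (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValueError("mesh contains degenerate faces")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class MeshReport:
    compartment: int
    is_watertight: bool
    n_components: int
    euler_characteristic: int
    surface_area_mm2: float
    enclosed_volume_mm3: float
    min_wall_thickness_mm: float | None = None
    notes: list[str] = field(default_factory=list)


def extract_shell(mask: np.ndarray) -> np.ndarray:
    """One-voxel-thick interface shell of a binary compartment mask.

    A voxel belongs to the shell when it is in the compartment and has at
    least one 26-neighbor (vertex-, edge- or face-adjacent) outside it;
    interior voxels are excluded.  Idempotent on one-voxel-thick sets.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot extract the shell of an empty compartment")
    outside = ~mask
    touches_outside = ndimage.binary_dilation(outside, structure=_VERTEX_STRUCT)
    return mask & touches_outside


def voxels_to_mesh(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    compartment: int = -1,
) -> SurfaceMesh:
    """Marching-cubes surface of a binary mask at iso-level 0.5.

    The mask is padded by one background voxel on every side first, so masks
    touching the grid boundary still produce a closed surface.  Faces are
    oriented outward (positive enclosed volume).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    spacing = tuple(float(s) for s in spacing)
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing) + np.asarray(origin_mm)  # undo padding shift
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        faces = faces[:, ::-1]
    return SurfaceMesh(vertices=verts, faces=faces, compartment=compartment)


def remove_noise_shells(mesh: SurfaceMesh, min_area_mm2: float = 50.0) -> SurfaceMesh:
    """Drop disconnected mesh components with area below ``min_area_mm2``.

    The largest-area component is always retained regardless of threshold.
    """
    tm = mesh.as_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1 or min_area_mm2 <= 0:
        return mesh
    areas = np.array([p.area for p in parts])
    keep = (areas >= min_area_mm2) | (areas == areas.max())
    kept = trimesh.util.concatenate([p for p, k in zip(parts, keep) if k])
    return SurfaceMesh(
        vertices=np.asarray(kept.vertices),
        faces=np.asarray(kept.faces),
        compartment=mesh.compartment,
    )


def _min_wall_thickness_mm(
    masks: dict[int, np.ndarray], spacing: tuple[float, float, float]
) -> dict[int, float]:
    """Per compartment: minimum center-to-center distance to any other
    compartment's voxels, via Euclidean distance transform on the grid."""
    out: dict[int, float] = {}
    labels = list(masks)
    for lbl in labels:
        others = np.zeros_like(masks[lbl])
        for o in labels:
            if o != lbl:
                others |= masks[o]
        if not others.any():
            out[lbl] = float("inf")
            continue
        dist = ndimage.distance_transform_edt(~others, sampling=spacing)
        out[lbl] = float(dist[masks[lbl]].min())
    return out


def validate_mesh(
    meshes: dict[int, SurfaceMesh],
    masks: dict[int, np.ndarray] | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> list[MeshReport]:
    """Printability report per compartment mesh; reports, never throws.

    With ``masks`` and ``spacing`` given, the minimum wall thickness between
    compartments is measured on the voxel grid (distance transform).
    """
    walls = (
        _min_wall_thickness_mm(masks, spacing) if masks is not None and spacing else {}
    )
    reports = []
    for lbl, mesh in meshes.items():
        tm = mesh.as_trimesh()
        notes = []
        vol = float(tm.volume)
        if tm.is_watertight and vol <= 0:
            notes.append("inward orientation: negative enclosed volume")
        reports.append(
            MeshReport(
                compartment=lbl,
                is_watertight=bool(tm.is_watertight),
                n_components=int(tm.body_count),
                euler_characteristic=int(tm.euler_number),
                surface_area_mm2=float(tm.area),
                enclosed_volume_mm3=abs(vol),
                min_wall_thickness_mm=walls.get(lbl),
                notes=notes,
            )
        )
    return reports


def write_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Export as binary STL (80-byte header, uint32 count, 50-byte records)."""
    Path(path).write_bytes(
        trimesh.exchange.stl.export_stl(mesh.as_trimesh())
    )


def read_stl(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="stl", process=False)
    tm.merge_vertices()  # STL stores an unindexed triangle soup
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def extract_compartment_meshes(
    model,
    noise_threshold_mm2: float = 50.0,
) -> dict[int, SurfaceMesh]:
    """Marching-cubes meshes of every non-background compartment of a built
    model, with noise shells below ``noise_threshold_mm2`` removed."""
    vol = model.labels
    meshes: dict[int, SurfaceMesh] = {}
    for lbl in sorted(vol.counts()):
        if lbl == BACKGROUND:
            continue
        mesh = voxels_to_mesh(vol.data == lbl, vol.voxel_size_mm, compartment=lbl)
        meshes[lbl] = remove_noise_shells(mesh, noise_threshold_mm2)
    return meshes
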
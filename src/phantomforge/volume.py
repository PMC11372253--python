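"""Voxel-volume containers and NIfTI I/O.

Two containers cover every pipeline stage: :class:`LabelVolume` for integer
tissue/compartment label maps and :class:`ActivityVolume` for floating-point
activity-concentration grids (kBq/mL).  Both carry per-axis voxel spacing and
a voxel→world affine; world coordinates are millimetres throughout, voxel
indices are 0-based, and voxel extents are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "LabelVolume",
    "ActivityVolume",
    "read_volume",
    "write_volume",
]

#: canonical compartment labels used across the pipeline
BACKGROUND, GM, WM, STRIATUM = 0, 1, 2, 3

COMPARTMENT_NAMES = {BACKGROUND: "background", GM: "GM", WM: "WM", STRIATUM: "striatum"}


def _default_affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _check_affine(affine: np.ndarray, voxel_size_mm: tuple[float, float, float]) -> None:
    col_norms = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(col_norms, voxel_size_mm, rtol=1e-6, atol=1e-9):
        raise ValueError(
            f"affine column norms {col_norms} inconsistent with voxel size {voxel_size_mm}"
        )


@dataclass
class LabelVolume:
    """3D integer label grid with spacing, affine and a label↔name table."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None
    label_table: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError("label volume data must be integer")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_affine(self.affine, self.voxel_size_mm)
        if not self.label_table:
            self.label_table = {
                int(l): COMPARTMENT_NAMES.get(int(l), f"label_{int(l)}")
                for l in np.unique(self.data)
            }
        extra = set(np.unique(self.data).tolist()) - set(self.label_table)
        if extra:
            raise ValueError(f"labels {sorted(extra)} missing from label_table")

    # -- geometry -----------------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of voxel indices to world mm."""
        ijk = np.atleast_2d(ijk)
        return (self.affine[:3, :3] @ ijk.T).T + self.affine[:3, 3]

    # -- label bookkeeping --------------------------------------------------
    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def counts(self) -> dict[int, int]:
        labels, n = np.unique(self.data, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, n)}

    def copy_with(self, data: np.ndarray, **meta) -> "LabelVolume":
        return LabelVolume(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            affine=self.affine.copy(),
            label_table=dict(self.label_table),
            meta={**self.meta, **meta},
        )

    # -- I/O ----------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        write_volume(self, path)


@dataclass
class ActivityVolume:
    """3D activity-concentration grid in kBq/mL."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("activity volume must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("activity values must be finite")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        _check_affine(self.affine, self.voxel_size_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def total_activity_kBq(self) -> float:
        """Total activity = sum(concentration) × voxel volume (mL)."""
        return float(self.data.sum() * self.voxel_volume_mm3 / 1000.0)

    def copy_with(self, data: np.ndarray, **provenance) -> "ActivityVolume":
        return ActivityVolume(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            affine=self.affine.copy(),
            provenance={**self.provenance, **provenance},
        )

    def save(self, path: str | Path) -> None:
        write_volume(self, path)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def write_volume(vol: LabelVolume | ActivityVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; label tables go to a JSON sidecar."""
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = np.asarray(vol.data, dtype=np.int32)
        img = nib.Nifti1Image(data, vol.affine)
        img.header.set_zooms(vol.voxel_size_mm)
        nib.save(img, path)
        _sidecar_path(path).write_text(
            json.dumps({str(k): v for k, v in vol.label_table.items()}, indent=1)
        )
    else:
        img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
        img.header.set_zooms(vol.voxel_size_mm)
        nib.save(img, path)


def read_volume(path: str | Path) -> LabelVolume | ActivityVolume:
    """Load a NIfTI-1 volume.

    Integer on-disk dtype dispatches to :class:`LabelVolume` (label table read
    from the ``.labels.json`` sidecar when present), floating point to
    :class:`ActivityVolume`.  When the header zooms disagree with the affine,
    the affine wins and a warning is attached to ``meta``/``provenance``.
    """
    path = Path(path)
    img = nib.load(path)
    affine = np.asarray(img.affine, dtype=float)
    spacing = tuple(float(v) for v in np.linalg.norm(affine[:3, :3], axis=0))
    zooms = tuple(float(v) for v in img.header.get_zooms()[:3])
    warning = None
    if not np.allclose(zooms, spacing, rtol=1e-4):
        warning = f"header zooms {zooms} disagree with affine spacing {spacing}; affine wins"
        import warnings

        warnings.warn(warning)
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        table: dict[int, str] = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            table = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        vol = LabelVolume(
            data=data.astype(np.int32),
            voxel_size_mm=spacing,
            affine=affine,
            label_table=table,
        )
        if warning:
            vol.meta["warning"] = warning
        return vol
    act = ActivityVolume(data=data.astype(np.float64), voxel_size_mm=spacing, affine=affine)
    if warning:
        act.provenance["warning"] = warning
    return act
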
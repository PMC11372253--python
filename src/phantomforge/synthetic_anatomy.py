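"""Seeded synthetic brain anatomy for the fillable three-compartment phantom.

Generates label volumes with the topology the downstream construction rules
operate on: a closed cortical gray-matter (GM) rind enclosing a white-matter
(WM) core, four striatal bodies (left/right caudate and putamen) embedded in
the WM, optional deep-nuclei sub-labels (pallidum, dentate, thalamus,
substantia nigra, red nucleus analogues), and deliberately disconnected
single-voxel islands that exercise the island-reassignment rule.

The geometry is ellipsoidal rather than gyrified: every construction rule in
the pipeline depends only on topology (nested compartments, connectivity,
islands), and simple quadric shapes keep the volume/area oracles analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, GM, STRIATUM, WM, LabelVolume

__all__ = ["AnatomyParams", "generate_anatomy", "DEFAULT_LABEL_TABLE", "SUB_LABELS"]

# sub-labels (≥ 10) for structures that the merge table folds into compartments
SUB_LABELS = {
    10: "caudate_left",
    11: "caudate_right",
    12: "putamen_left",
    13: "putamen_right",
    20: "pallidum",
    21: "dentate_nucleus",
    22: "thalamus",
    23: "substantia_nigra",
    24: "red_nucleus",
    4: "csf",
    5: "extracranial",
}

DEFAULT_LABEL_TABLE = {
    BACKGROUND: "background",
    GM: "GM",
    WM: "WM",
    STRIATUM: "striatum",
    **SUB_LABELS,
}

# (sub_label, center offset from brain center in mm, radius mm); bilateral
# structures appear once per side.  All lie strictly inside the WM core of the
# default brain radii.
_DEFAULT_DEEP_NUCLEI = [
    (20, (18.0, -2.0, -2.0), 4.0),
    (20, (-18.0, -2.0, -2.0), 4.0),
    (21, (12.0, -30.0, -20.0), 4.0),
    (21, (-12.0, -30.0, -20.0), 4.0),
    (22, (9.0, -16.0, -2.0), 5.0),
    (22, (-9.0, -16.0, -2.0), 5.0),
    (23, (7.0, -8.0, -14.0), 2.5),
    (23, (-7.0, -8.0, -14.0), 2.5),
    (24, (4.0, -10.0, -12.0), 2.0),
    (24, (-4.0, -10.0, -12.0), 2.0),
]

# caudate and putamen semi-axes/centres, one entry per body
_DEFAULT_STRIATUM = {
    10: ((14.0, 8.0, 6.0), (4.0, 12.0, 5.0)),
    11: ((-14.0, 8.0, 6.0), (4.0, 12.0, 5.0)),
    12: ((24.0, -4.0, 2.0), (5.5, 14.0, 6.5)),
    13: ((-24.0, -4.0, 2.0), (5.5, 14.0, 6.5)),
}


@dataclass
class AnatomyParams:
    """Parameters of the synthetic anatomy generator.

    ``voxel_size_mm`` defaults to the 0.9375 × 0.9375 × 1 mm grid convention
    of MR-derived digital phantoms; ``grid_shape`` 160³ keeps default builds
    desk-sized (256³ works for full-scale runs).
    """

    grid_shape: tuple[int, int, int] = (160, 160, 160)
    voxel_size_mm: tuple[float, float, float] = (0.9375, 0.9375, 1.0)
    brain_radii_mm: tuple[float, float, float] = (60.0, 52.0, 55.0)
    gm_rind_thickness_mm: float = 6.0
    striatum_bodies: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_STRIATUM)
    )
    deep_nuclei_spec: list[tuple[int, tuple[float, float, float], float]] = field(
        default_factory=lambda: list(_DEFAULT_DEEP_NUCLEI)
    )
    n_islands: int = 4
    seed: int = 0

    def scaled(self, factor: float) -> "AnatomyParams":
        """Uniformly shrink/grow all mm geometry (grid and voxels unchanged).

        Handy for desk-scale runs on coarse grids: every radius, thickness
        and center offset is multiplied by ``factor``.
        """
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return AnatomyParams(
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
            brain_radii_mm=tuple(r * factor for r in self.brain_radii_mm),
            gm_rind_thickness_mm=self.gm_rind_thickness_mm * factor,
            striatum_bodies={
                lbl: (
                    tuple(c * factor for c in center),
                    tuple(r * factor for r in radii),
                )
                for lbl, (center, radii) in self.striatum_bodies.items()
            },
            deep_nuclei_spec=[
                (lbl, tuple(c * factor for c in center), radius * factor)
                for lbl, center, radius in self.deep_nuclei_spec
            ],
            n_islands=self.n_islands,
            seed=self.seed,
        )

    def validate(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if any(r <= 0 for r in self.brain_radii_mm):
            raise ValueError("brain radii must be positive")
        if not 0 < self.gm_rind_thickness_mm < min(self.brain_radii_mm):
            raise ValueError("gm_rind_thickness_mm must be in (0, min(brain_radii_mm))")
        inner = np.asarray(self.brain_radii_mm) - self.gm_rind_thickness_mm
        for lbl, (center, radii) in self.striatum_bodies.items():
            if any(r <= 0 for r in radii):
                raise ValueError(f"striatal body {lbl}: radii must be positive")
            # bounding-box corner test: body must sit strictly inside the WM core
            reach = np.abs(np.asarray(center)) + np.asarray(radii)
            if np.sum((reach / inner) ** 2) >= 1.0:
                raise ValueError(
                    f"striatal body {lbl} intersects the GM shell or exits the WM core"
                )
        for lbl, center, radius in self.deep_nuclei_spec:
            if lbl not in SUB_LABELS:
                raise ValueError(f"unknown deep-nucleus sub-label {lbl}")
            if radius <= 0:
                raise ValueError("deep-nucleus radius must be positive")
        if self.n_islands < 0:
            raise ValueError("n_islands must be >= 0")


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    """Voxels whose centers lie inside the ellipsoid (world mm)."""
    axes = [
        ((np.arange(n) + 0.5) * v - c) / r
        for n, v, c, r in zip(shape, voxel, center_mm, radii_mm)
    ]
    q = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    return q < 1.0


def _inject_islands(
    data: np.ndarray,
    island_label: int,
    host_label: int,
    n: int,
    rng: np.random.Generator,
) -> list[tuple[int, int, int]]:
    """Place ``n`` single-voxel islands of ``island_label`` inside ``host_label``.

    Sites keep a Chebyshev distance ≥ 2 from every non-host voxel, so each
    island is disconnected from its own tissue under 26-connectivity, and a
    pairwise separation ≥ 3 so islands never merge with each other.
    """
    if n == 0:
        return []
    host = data == host_label
    # candidate = whole Chebyshev-radius-2 neighborhood is host tissue
    candidates = ndimage.binary_erosion(host, structure=np.ones((5, 5, 5), bool))
    coords = np.argwhere(candidates)
    if len(coords) < n:
        raise ValueError(
            f"not enough room for {n} islands of label {island_label} in label {host_label}"
        )
    order = rng.permutation(len(coords))
    chosen: list[tuple[int, int, int]] = []
    for idx in order:
        c = coords[idx]
        if all(np.max(np.abs(c - np.asarray(p))) >= 3 for p in chosen):
            chosen.append(tuple(int(x) for x in c))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError("could not place the requested number of separated islands")
    for c in chosen:
        data[c] = island_label
    return chosen


def generate_anatomy(params: AnatomyParams) -> LabelVolume:
    """Build a synthetic label volume per ``params``.

    The returned volume records island coordinates in ``meta['islands']``
    (``{'GM': [...], 'WM': [...]}``, voxel indices).  A fixed seed gives a
    bit-identical volume.
    """
    params.validate()
    shape = tuple(params.grid_shape)
    voxel = params.voxel_size_mm
    extent = np.asarray(shape) * np.asarray(voxel)
    center = extent / 2.0
    outer = np.asarray(params.brain_radii_mm, dtype=float)
    inner = outer - params.gm_rind_thickness_mm
    if np.any(outer * 2 >= extent):
        raise ValueError("brain does not fit inside the grid with margin")

    data = np.zeros(shape, dtype=np.int32)
    brain = _ellipsoid_mask(shape, voxel, center, outer)
    core = _ellipsoid_mask(shape, voxel, center, inner)
    data[brain] = GM
    data[core] = WM

    for lbl, (off, radii) in params.striatum_bodies.items():
        body = _ellipsoid_mask(shape, voxel, center + np.asarray(off), np.asarray(radii))
        if np.any(body & (data != WM)):
            raise ValueError(f"striatal body {lbl} leaves the WM core")
        data[body] = lbl

    for lbl, off, radius in params.deep_nuclei_spec:
        nucleus = _ellipsoid_mask(
            shape, voxel, center + np.asarray(off), np.full(3, float(radius))
        )
        if np.any(nucleus & (data == BACKGROUND)) or np.any(nucleus & (data == GM)):
            raise ValueError(f"deep nucleus {lbl} leaves the brain interior")
        nucleus &= data == WM  # never clobber striatum or other nuclei
        data[nucleus] = lbl

    rng = np.random.default_rng(params.seed)
    islands = {
        "GM": _inject_islands(data, GM, WM, params.n_islands, rng),
        "WM": _inject_islands(data, WM, GM, params.n_islands, rng),
    }

    table = {
        k: v
        for k, v in DEFAULT_LABEL_TABLE.items()
        if k in {BACKGROUND, GM, WM}
        or k in params.striatum_bodies
        or k in {lbl for lbl, _, _ in params.deep_nuclei_spec}
    }
    return LabelVolume(
        data=data,
        voxel_size_mm=voxel,
        label_table=table,
        meta={
            "islands": islands,
            "brain_center_mm": center.tolist(),
            "brain_radii_mm": list(outer),
            "gm_rind_thickness_mm": params.gm_rind_thickness_mm,
            "seed": params.seed,
        },
    )
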
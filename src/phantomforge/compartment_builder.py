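"""Construction rules turning a raw label volume into the fillable phantom model.

The stages mirror the physical phantom's design workflow:

1. **merge** sub-labels into the four compartments (background, GM, WM,
   striatum): deep GM nuclei (pallidum, dentate, thalamus) go to GM,
   substantia nigra and red nucleus to WM, caudate and putamen to the
   striatum, CSF/extracranial tissue to the background;
2. **reassign islands**: GM or WM voxels 3D-disconnected from their main
   tissue component are absorbed into the surrounding prevalent tissue;
3. **connect** the striatal bodies into one fillable compartment with 5-mm
   lumen cylinders and add two bilateral 6-mm fill pipes per compartment,
   reaching down from above the apical surface;
4. **supersample** to print resolution (0.75 mm isotropic default) by
   nearest-neighbor interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, GM, STRIATUM, WM, LabelVolume

__all__ = [
    "DEFAULT_MERGE_TABLE",
    "CompartmentModel",
    "PipeSpec",
    "merge_labels",
    "reassign_islands",
    "add_cylinder",
    "supersample",
    "build_compartments",
]

# sub-label → compartment assignments of the phantom design
DEFAULT_MERGE_TABLE: dict[int, int] = {
    BACKGROUND: BACKGROUND,
    GM: GM,
    WM: WM,
    STRIATUM: STRIATUM,
    4: BACKGROUND,  # CSF
    5: BACKGROUND,  # extracranial tissue
    10: STRIATUM,  # caudate L
    11: STRIATUM,  # caudate R
    12: STRIATUM,  # putamen L
    13: STRIATUM,  # putamen R
    20: GM,  # pallidum
    21: GM,  # dentate nucleus
    22: GM,  # thalamus
    23: WM,  # substantia nigra
    24: WM,  # red nucleus
}

_COMPARTMENT_TABLE = {BACKGROUND: "background", GM: "GM", WM: "WM", STRIATUM: "striatum"}

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class PipeSpec:
    """A cylindrical pipe or connector to rasterize into the model.

    ``allowed_crossings`` lists the labels the cylinder may pass through and
    relabel; hitting any other label is an error (compartments must stay
    disjoint unless the crossing is deliberate).  ``threaded_joint`` is
    metadata only — thread geometry is not modeled.
    """

    lumen_diameter_mm: float
    target_label: int
    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    kind: str = "pipe"  # or "connector"
    allowed_crossings: frozenset[int] = frozenset({BACKGROUND})
    threaded_joint: bool = True

    def validate(self, voxel_size_mm: tuple[float, float, float]) -> None:
        if self.lumen_diameter_mm <= 2 * max(voxel_size_mm):
            raise ValueError(
                f"lumen {self.lumen_diameter_mm} mm must exceed twice the voxel size"
            )


@dataclass
class CompartmentModel:
    """The built phantom: compartment labels plus pipe/connector provenance."""

    labels: LabelVolume
    pipe_mask: np.ndarray
    connector_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        return self.labels.voxel_size_mm

    def compartment_mask(self, label: int) -> np.ndarray:
        return self.labels.data == label


def merge_labels(vol: LabelVolume, table: dict[int, int] | None = None) -> LabelVolume:
    """Map every sub-label to its compartment; unmapped labels are an error."""
    table = DEFAULT_MERGE_TABLE if table is None else table
    present = np.unique(vol.data)
    unmapped = [int(l) for l in present if int(l) not in table]
    if unmapped:
        raise ValueError(f"merge table does not map labels {unmapped}")
    lut = np.zeros(int(present.max()) + 1, dtype=vol.data.dtype)
    for src in present:
        lut[int(src)] = table[int(src)]
    merged = lut[vol.data]
    return LabelVolume(
        data=merged,
        voxel_size_mm=vol.voxel_size_mm,
        affine=vol.affine.copy(),
        label_table={int(l): _COMPARTMENT_TABLE[int(l)] for l in np.unique(merged)},
        meta={**vol.meta, "merge_table": {int(k): int(v) for k, v in table.items()}},
    )


def _components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=_STRUCTS[connectivity])


def reassign_islands(
    vol: LabelVolume,
    connectivity: int = 26,
    labels: tuple[int, ...] | None = None,
    max_iter: int = 100,
) -> LabelVolume:
    """Absorb disconnected islands into the surrounding prevalent tissue.

    For each tissue in ``labels`` (default: every non-background label
    present) the largest connected component under ``connectivity`` is kept
    as the main body; every other voxel of that tissue takes the majority
    label among its face-adjacent non-background neighbors, iterating until
    no island remains.  Ties break by fixed label order (GM < WM < striatum).
    Total non-background voxel count is conserved.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    data = vol.data.copy()
    if labels is None:
        labels = tuple(int(l) for l in np.unique(data) if l != BACKGROUND)
    face = _STRUCTS[6]
    n_reassigned = 0
    for _ in range(max_iter):
        island = np.zeros(data.shape, dtype=bool)
        for lbl in labels:
            mask = data == lbl
            if not mask.any():
                continue
            comp, n = _components(mask, connectivity)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
            main = int(np.argmax(sizes)) + 1  # ties: lowest component index
            island |= mask & (comp != main)
        if not island.any():
            break
        # majority vote over face neighbors of the *surrounding* tissue —
        # island voxels do not vote, so thick islands erode outside-in over
        # iterations; lowest label wins ties
        surround = data.copy()
        surround[island] = BACKGROUND
        votes = []
        present = sorted(int(l) for l in np.unique(surround) if l != BACKGROUND)
        for lbl in present:
            neigh = ndimage.convolve(
                (surround == lbl).astype(np.int16), face.astype(np.int16), mode="constant"
            )
            votes.append(neigh)
        votes = np.stack(votes)  # (L, *shape)
        idx = np.argwhere(island)
        vote_block = votes[:, idx[:, 0], idx[:, 1], idx[:, 2]]
        has_neighbor = vote_block.sum(axis=0) > 0
        winners = np.asarray(present)[np.argmax(vote_block, axis=0)]
        changed = False
        for (i, j, k), w, ok in zip(idx, winners, has_neighbor):
            if ok and w != data[i, j, k]:
                data[i, j, k] = w
                n_reassigned += 1
                changed = True
        if not changed:
            raise RuntimeError(
                "island reassignment stalled: island voxels without resolvable "
                "non-background neighborhood (pathological input)"
            )
    else:
        raise RuntimeError(f"island reassignment did not converge in {max_iter} iterations")
    return vol.copy_with(data, islands_reassigned=n_reassigned)


def _cylinder_mask(
    shape: tuple[int, int, int],
    voxel: tuple[float, float, float],
    p0: np.ndarray,
    p1: np.ndarray,
    radius_mm: float,
) -> np.ndarray:
    """Voxels whose centers lie within ``radius_mm`` of segment p0–p1 (world mm)."""
    voxel = np.asarray(voxel)
    lo = np.minimum(p0, p1) - radius_mm
    hi = np.maximum(p0, p1) + radius_mm
    i0 = np.maximum(np.floor(lo / voxel - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / voxel - 0.5).astype(int) + 1, shape)
    out = np.zeros(shape, dtype=bool)
    if np.any(i0 >= i1):
        return out
    grids = np.meshgrid(
        *[(np.arange(a, b) + 0.5) * v for a, b, v in zip(i0, i1, voxel)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0.0:  # zero-length cylinder has no volume
        return out
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    dist2 = np.sum((pts - proj) ** 2, axis=-1)
    out[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] = dist2 <= radius_mm**2
    return out


def add_cylinder(model: CompartmentModel, spec: PipeSpec) -> CompartmentModel:
    """Rasterize a pipe/connector into the model, relabeling allowed crossings.

    Voxels inside the lumen become ``spec.target_label`` and are recorded in
    the pipe or connector mask; a voxel holding any label outside
    ``allowed_crossings ∪ {target}`` aborts the operation.
    """
    vol = model.labels
    spec.validate(vol.voxel_size_mm)
    p0 = np.asarray(spec.start_mm, dtype=float)
    p1 = np.asarray(spec.end_mm, dtype=float)
    cyl = _cylinder_mask(vol.data.shape, vol.voxel_size_mm, p0, p1, spec.lumen_diameter_mm / 2)
    if not cyl.any():
        return model  # zero-length/degenerate cylinder: no-op
    hit = set(int(l) for l in np.unique(vol.data[cyl]))
    bad = hit - set(spec.allowed_crossings) - {spec.target_label}
    if bad:
        raise ValueError(
            f"{spec.kind} to label {spec.target_label} would relabel voxels of "
            f"compartments {sorted(bad)}"
        )
    data = vol.data.copy()
    added = cyl & (data != spec.target_label)
    data[cyl] = spec.target_label
    if spec.target_label not in vol.label_table:
        vol = LabelVolume(
            data=vol.data,
            voxel_size_mm=vol.voxel_size_mm,
            affine=vol.affine.copy(),
            label_table={
                **vol.label_table,
                int(spec.target_label): _COMPARTMENT_TABLE.get(
                    int(spec.target_label), f"label_{int(spec.target_label)}"
                ),
            },
            meta=vol.meta,
        )
    pipe_mask = model.pipe_mask.copy()
    connector_mask = model.connector_mask.copy()
    if spec.kind == "connector":
        connector_mask |= added
    else:
        pipe_mask |= added
    prov = dict(model.provenance)
    prov.setdefault("cylinders", []).append(
        {
            "kind": spec.kind,
            "target": int(spec.target_label),
            "lumen_mm": spec.lumen_diameter_mm,
            "voxels_added": int(added.sum()),
        }
    )
    return CompartmentModel(
        labels=vol.copy_with(data),
        pipe_mask=pipe_mask,
        connector_mask=connector_mask,
        provenance=prov,
    )


def supersample(vol: LabelVolume, target_voxel_mm: float | tuple[float, float, float]) -> LabelVolume:
    """Nearest-neighbor resample to ``target_voxel_mm`` over the same world extent."""
    if np.isscalar(target_voxel_mm):
        target = (float(target_voxel_mm),) * 3
    else:
        target = tuple(float(v) for v in target_voxel_mm)
    if any(v <= 0 for v in target):
        raise ValueError("target voxel size must be positive")
    src = vol.voxel_size_mm
    shape = vol.data.shape
    extent = [n * s for n, s in zip(shape, src)]
    out_shape = tuple(int(round(e / t)) for e, t in zip(extent, target))
    idx = []
    for n_out, n_in, t, s in zip(out_shape, shape, target, src):
        centers = (np.arange(n_out) + 0.5) * t
        nearest = np.floor(centers / s).astype(int)  # voxel containing the center
        idx.append(np.clip(nearest, 0, n_in - 1))
    data = vol.data[np.ix_(*idx)]
    affine = vol.affine.copy()
    scale = np.asarray(target) / np.asarray(src)
    affine[:3, :3] = affine[:3, :3] * scale[None, :]
    return LabelVolume(
        data=data,
        voxel_size_mm=target,
        affine=affine,
        label_table=dict(vol.label_table),
        meta={**vol.meta, "supersampled_from_mm": list(src)},
    )


def _supersample_mask(mask: np.ndarray, src, target) -> np.ndarray:
    tmp = LabelVolume(mask.astype(np.int32), src)
    return supersample(tmp, target).data.astype(bool)


def _bilateral_entry_columns(mask: np.ndarray) -> list[tuple[int, int]]:
    """Two (i, j) columns, one per hemisphere, through thick apical tissue."""
    cols = mask.sum(axis=2)  # tissue depth per column
    top = np.zeros_like(cols)
    any_col = cols > 0
    # apical z per column
    kmax = np.where(any_col, mask.shape[2] - 1 - np.argmax(mask[:, :, ::-1], axis=2), -1)
    entries = []
    mid = mask.shape[0] // 2
    for side in (slice(0, mid), slice(mid, None)):
        sub = cols[side]
        if not sub.any():
            raise ValueError("compartment absent from one hemisphere; cannot place pipe")
        # choose the column with maximal apical surface height, then depth
        ksub = kmax[side]
        score = ksub * 10000 + np.minimum(sub, 9999)
        i, j = np.unravel_index(np.argmax(score), sub.shape)
        entries.append((int(i + (side.start or 0)), int(j)))
    return entries


def _add_fill_pipes(
    model: CompartmentModel,
    lumen_mm: float = 6.0,
    penetration_mm: float = 3.0,
) -> CompartmentModel:
    """Two bilateral z-aligned fill pipes per compartment, from the grid top
    down to ``penetration_mm`` below the compartment's apical surface."""
    voxel = np.asarray(model.voxel_size_mm)
    shape = model.labels.data.shape
    allowed = {
        GM: frozenset({BACKGROUND}),
        WM: frozenset({BACKGROUND, GM}),
        STRIATUM: frozenset({BACKGROUND, GM, WM}),
    }
    for target in (GM, WM, STRIATUM):
        mask = model.compartment_mask(target)
        if not mask.any():
            raise ValueError(f"compartment {target} empty; cannot add pipes")
        for i, j in _bilateral_entry_columns(mask):
            col = mask[i, j, :]
            k_top = int(np.max(np.nonzero(col)[0]))
            x = (i + 0.5) * voxel[0]
            y = (j + 0.5) * voxel[1]
            z_top = shape[2] * voxel[2]  # reach from the top of the volume
            # thin or strongly curved apical walls tolerate less penetration:
            # back off until the pipe stays out of deeper compartments
            pen = penetration_mm
            for _ in range(8):
                z_bot = (k_top + 0.5) * voxel[2] - pen
                spec = PipeSpec(
                    lumen_diameter_mm=lumen_mm,
                    target_label=target,
                    start_mm=(x, y, z_top),
                    end_mm=(x, y, z_bot),
                    kind="pipe",
                    allowed_crossings=allowed[target],
                )
                try:
                    model = add_cylinder(model, spec)
                    break
                except ValueError:
                    pen /= 2.0
            else:
                raise ValueError(
                    f"cannot place a fill pipe into compartment {target} without "
                    "crossing another compartment"
                )
    return model


def _connect_striatum(
    model: CompartmentModel, lumen_mm: float = 5.0, connectivity: int = 26
) -> CompartmentModel:
    """Join all striatal bodies into one component with cylindric connectors."""
    voxel = np.asarray(model.voxel_size_mm)
    for _ in range(16):
        mask = model.compartment_mask(STRIATUM)
        comp, n = _components(mask, connectivity)
        if n <= 1:
            return model
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1] + 1
        main, second = int(order[0]), int(order[1])
        c_main = (np.asarray(ndimage.center_of_mass(comp == main)) + 0.5) * voxel
        c_sec = (np.asarray(ndimage.center_of_mass(comp == second)) + 0.5) * voxel
        spec = PipeSpec(
            lumen_diameter_mm=lumen_mm,
            target_label=STRIATUM,
            start_mm=tuple(c_main),
            end_mm=tuple(c_sec),
            kind="connector",
            allowed_crossings=frozenset({WM}),
        )
        model = add_cylinder(model, spec)
    raise RuntimeError("failed to unify striatum within connector budget")


def build_compartments(
    anatomy: LabelVolume,
    merge_table: dict[int, int] | None = None,
    print_voxel_mm: float | tuple[float, float, float] = 0.75,
    connectivity: int = 26,
    pipe_lumen_mm: float = 6.0,
    connector_lumen_mm: float = 5.0,
    add_pipes: bool = True,
) -> CompartmentModel:
    """Full build: merge → reassign islands → connectors → pipes → supersample.

    Post-condition (asserted): exactly three non-background compartments, each
    a single 26-connected component.
    """
    merged = merge_labels(anatomy, merge_table)
    n_nonbg_before = int((merged.data != BACKGROUND).sum())
    fixed = reassign_islands(merged, connectivity=connectivity, labels=(GM, WM))
    n_nonbg_after = int((fixed.data != BACKGROUND).sum())
    if n_nonbg_before != n_nonbg_after:
        raise RuntimeError("island reassignment changed the non-background voxel count")

    model = CompartmentModel(
        labels=fixed,
        pipe_mask=np.zeros(fixed.data.shape, dtype=bool),
        connector_mask=np.zeros(fixed.data.shape, dtype=bool),
        provenance={
            "merged_counts": merged.counts(),
            "islands_reassigned": fixed.meta.get("islands_reassigned", 0),
        },
    )
    model = _connect_striatum(model, lumen_mm=connector_lumen_mm, connectivity=connectivity)
    if add_pipes:
        model = _add_fill_pipes(model, lumen_mm=pipe_lumen_mm)
        # pipes carving through curved walls can strand small tissue crumbs;
        # the island rule absorbs them like any other disconnected island
        cleaned = reassign_islands(model.labels, connectivity=connectivity, labels=(GM, WM))
        model.provenance["islands_reassigned_after_pipes"] = cleaned.meta.get(
            "islands_reassigned", 0
        )
        model = CompartmentModel(
            labels=cleaned,
            pipe_mask=model.pipe_mask,
            connector_mask=model.connector_mask,
            provenance=model.provenance,
        )

    src = model.labels.voxel_size_mm
    hi = supersample(model.labels, print_voxel_mm)
    pipe_hi = _supersample_mask(model.pipe_mask, src, print_voxel_mm)
    conn_hi = _supersample_mask(model.connector_mask, src, print_voxel_mm)
    model = CompartmentModel(
        labels=hi,
        pipe_mask=pipe_hi,
        connector_mask=conn_hi,
        provenance={**model.provenance, "print_voxel_mm": print_voxel_mm},
    )
    for lbl in (GM, WM, STRIATUM):
        mask = model.compartment_mask(lbl)
        if not mask.any():
            raise RuntimeError(f"compartment {lbl} empty after build")
        _, n = _components(mask, connectivity)
        if n != 1:
            raise RuntimeError(
                f"compartment {lbl} has {n} connected components after build"
            )
    model.provenance["compartment_counts"] = model.labels.counts()
    return model
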
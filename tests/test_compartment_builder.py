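"""Construction rules: merging, island reassignment, cylinders, supersampling."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from phantomforge import (
    BACKGROUND,
    GM,
    STRIATUM,
    WM,
    LabelVolume,
    add_cylinder,
    build_compartments,
    generate_anatomy,
    merge_labels,
    reassign_islands,
    supersample,
)
from phantomforge.compartment_builder import (
    DEFAULT_MERGE_TABLE,
    CompartmentModel,
    PipeSpec,
)

from conftest import small_anatomy_params

STRUCT26 = np.ones((3, 3, 3), bool)


def flood_fill_components(mask: np.ndarray) -> int:
    """Independent 26-connected component counter (BFS, no scipy)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    n = 0
    shape = mask.shape
    for start in map(tuple, np.argwhere(mask & ~seen)):
        if seen[start]:
            continue
        n += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if (
                    0 <= p[0] < shape[0]
                    and 0 <= p[1] < shape[1]
                    and 0 <= p[2] < shape[2]
                    and mask[p]
                    and not seen[p]
                ):
                    seen[p] = True
                    queue.append(p)
    return n


# --------------------------------------------------------------------------
# merge_labels
# --------------------------------------------------------------------------
class TestMergeLabels:
    def test_design_assignments(self):
        """Caudate/putamen → striatum, pallidum/dentate/thalamus → GM,
        substantia nigra/red nucleus → WM, CSF/extracranial → background."""
        data = np.array([[[0, 1, 2, 4, 5, 10, 11, 12, 13, 20, 21, 22, 23, 24]]], dtype=np.int32)
        vol = LabelVolume(data, (1, 1, 1), label_table={i: f"l{i}" for i in range(25)})
        merged = merge_labels(vol)
        expect = [0, 1, 2, 0, 0, 3, 3, 3, 3, 1, 1, 1, 2, 2]
        assert merged.data.ravel().tolist() == expect

    def test_identity_on_merged_volume(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32)
        vol = LabelVolume(data, (1, 1, 1))
        out = merge_labels(vol, {0: 0, 1: 1, 2: 2, 3: 3})
        assert np.array_equal(out.data, data)

    def test_counts_sum_over_sub_labels(self):
        """Per-compartment counts equal the sum of mapped sub-label tallies."""
        vol = generate_anatomy(small_anatomy_params(n_islands=0))
        before = vol.counts()
        merged = merge_labels(vol)
        after = merged.counts()
        for comp in (BACKGROUND, GM, WM, STRIATUM):
            expected = sum(
                n for lbl, n in before.items() if DEFAULT_MERGE_TABLE[lbl] == comp
            )
            assert after.get(comp, 0) == expected

    def test_unmapped_label_is_hard_error(self):
        vol = LabelVolume(np.full((2, 2, 2), 99, dtype=np.int32), (1, 1, 1),
                          label_table={99: "mystery"})
        with pytest.raises(ValueError, match="99"):
            merge_labels(vol, {0: 0})


# --------------------------------------------------------------------------
# reassign_islands
# --------------------------------------------------------------------------
def _random_blob_volume(seed: int, n: int = 40) -> LabelVolume:
    """Random label volume with big blobs plus scattered stray voxels."""
    rng = np.random.default_rng(seed)
    data = np.zeros((n, n, n), dtype=np.int32)
    ax = np.arange(n)
    centers = rng.uniform(8, n - 8, size=(3, 3))
    radii = [10, 8, 6]
    for lbl, (c, r) in enumerate(zip(centers, radii), start=1):
        q = (
            (ax[:, None, None] - c[0]) ** 2
            + (ax[None, :, None] - c[1]) ** 2
            + (ax[None, None, :] - c[2]) ** 2
        )
        data[q < r**2] = lbl
    # stray single voxels of each label sprinkled into other tissue
    nonbg = np.argwhere(data > 0)
    for lbl in (1, 2, 3):
        for _ in range(10):
            i = rng.integers(len(nonbg))
            data[tuple(nonbg[i])] = lbl
    return LabelVolume(data, (1, 1, 1))


class TestReassignIslands:
    def test_identity_without_islands(self):
        # no islands and no deep nuclei: merging leaves nothing disconnected
        p = small_anatomy_params(n_islands=0)
        p.deep_nuclei_spec = []
        merged = merge_labels(generate_anatomy(p))
        out = reassign_islands(merged, labels=(GM, WM))
        assert np.array_equal(out.data, merged.data)

    def test_single_voxel_island_takes_surrounding_tissue(self):
        # main GM slab at the bottom; one stray GM voxel deep inside WM
        data = np.full((9, 9, 9), WM, dtype=np.int32)
        data[:, :, 0] = GM
        data[4, 4, 5] = GM
        out = reassign_islands(LabelVolume(data, (1, 1, 1)))
        assert out.data[4, 4, 5] == WM
        assert (out.data[:, :, 0] == GM).all()  # main component untouched

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_component_per_label_on_random_volume(self, seed):
        """Post-condition verified with an independent BFS flood fill."""
        vol = _random_blob_volume(seed)
        out = reassign_islands(vol)
        for lbl in (1, 2, 3):
            mask = out.data == lbl
            if mask.any():
                assert flood_fill_components(mask) == 1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_idempotent(self, seed):
        vol = _random_blob_volume(seed)
        once = reassign_islands(vol)
        twice = reassign_islands(once)
        assert np.array_equal(once.data, twice.data)

    def test_conserves_non_background_count(self):
        vol = _random_blob_volume(3)
        out = reassign_islands(vol)
        assert (out.data != 0).sum() == (vol.data != 0).sum()

    def test_invalid_connectivity_rejected(self):
        vol = _random_blob_volume(0)
        with pytest.raises(ValueError):
            reassign_islands(vol, connectivity=10)


# --------------------------------------------------------------------------
# add_cylinder
# --------------------------------------------------------------------------
def _two_body_model() -> CompartmentModel:
    """Two disjoint striatal balls inside a WM slab."""
    data = np.full((40, 40, 40), WM, dtype=np.int32)
    ax = np.arange(40) + 0.5
    for cx in (10.0, 30.0):
        q = (
            (ax[:, None, None] - cx) ** 2
            + (ax[None, :, None] - 20) ** 2
            + (ax[None, None, :] - 20) ** 2
        )
        data[q < 25] = STRIATUM
    vol = LabelVolume(data, (1, 1, 1))
    return CompartmentModel(
        labels=vol,
        pipe_mask=np.zeros(data.shape, bool),
        connector_mask=np.zeros(data.shape, bool),
    )


class TestAddCylinder:
    def test_connector_unifies_striatum(self):
        model = _two_body_model()
        _, n0 = ndimage.label(model.compartment_mask(STRIATUM), structure=STRUCT26)
        assert n0 == 2
        spec = PipeSpec(
            lumen_diameter_mm=5.0,
            target_label=STRIATUM,
            start_mm=(10, 20, 20),
            end_mm=(30, 20, 20),
            kind="connector",
            allowed_crossings=frozenset({WM}),
        )
        out = add_cylinder(model, spec)
        _, n1 = ndimage.label(out.compartment_mask(STRIATUM), structure=STRUCT26)
        assert n1 == 1
        assert out.connector_mask.sum() > 0
        assert not out.pipe_mask.any()

    def test_zero_length_cylinder_is_noop(self):
        model = _two_body_model()
        spec = PipeSpec(
            lumen_diameter_mm=5.0,
            target_label=STRIATUM,
            start_mm=(20, 20, 20),
            end_mm=(20, 20, 20),
            allowed_crossings=frozenset({WM}),
        )
        out = add_cylinder(model, spec)
        assert np.array_equal(out.labels.data, model.labels.data)

    def test_added_volume_matches_analytic_cylinder(self):
        """d=6 mm, L=40 mm at 0.75 mm voxels: voxel volume within 15% of πr²L."""
        shape = (80, 80, 80)
        vol = LabelVolume(np.zeros(shape, dtype=np.int32), (0.75, 0.75, 0.75))
        model = CompartmentModel(
            labels=vol,
            pipe_mask=np.zeros(shape, bool),
            connector_mask=np.zeros(shape, bool),
        )
        spec = PipeSpec(
            lumen_diameter_mm=6.0,
            target_label=GM,
            start_mm=(30.0, 30.0, 10.0),
            end_mm=(30.0, 30.0, 50.0),
        )
        out = add_cylinder(model, spec)
        measured = out.pipe_mask.sum() * vol.voxel_volume_mm3
        analytic = np.pi * 3.0**2 * 40.0
        assert abs(measured / analytic - 1.0) < 0.15

    def test_disallowed_crossing_is_error(self):
        model = _two_body_model()
        spec = PipeSpec(
            lumen_diameter_mm=5.0,
            target_label=STRIATUM,
            start_mm=(10, 20, 20),
            end_mm=(30, 20, 20),
            allowed_crossings=frozenset({BACKGROUND}),  # WM crossing not allowed
        )
        with pytest.raises(ValueError, match="relabel"):
            add_cylinder(model, spec)

    def test_narrow_lumen_rejected(self):
        spec = PipeSpec(
            lumen_diameter_mm=1.0,
            target_label=GM,
            start_mm=(0, 0, 0),
            end_mm=(0, 0, 10),
        )
        with pytest.raises(ValueError, match="lumen"):
            spec.validate((0.75, 0.75, 0.75))


# --------------------------------------------------------------------------
# supersample
# --------------------------------------------------------------------------
class TestSupersample:
    def test_identity_spacing(self):
        vol = generate_anatomy(small_anatomy_params(n_islands=0, grid=(48, 48, 48), voxel=(2.0, 2.0, 2.0)))
        out = supersample(vol, (2.0, 2.0, 2.0))
        assert np.array_equal(out.data, vol.data)

    def test_integer_upsampling_is_block_replication(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int32)
        vol = LabelVolume(data, (1.0, 1.0, 1.0))
        out = supersample(vol, 0.5)
        assert out.data.shape == (12, 12, 12)
        assert np.array_equal(out.data, np.kron(data, np.ones((2, 2, 2), dtype=np.int32)))

    def test_volume_preserved_to_print_resolution(self):
        """0.9375×0.9375×1 mm → 0.75³ mm preserves compartment volumes to 1%."""
        p = small_anatomy_params(
            n_islands=0, grid=(96, 96, 90), voxel=(0.9375, 0.9375, 1.0)
        )
        vol = generate_anatomy(p)
        hi = supersample(vol, 0.75)
        assert set(np.unique(hi.data)) == set(np.unique(vol.data))
        for lbl in (GM, WM):
            v0 = (vol.data == lbl).sum() * vol.voxel_volume_mm3
            v1 = (hi.data == lbl).sum() * hi.voxel_volume_mm3
            assert abs(v1 / v0 - 1.0) < 0.01

    def test_nonpositive_spacing_rejected(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError):
            supersample(vol, 0.0)


# --------------------------------------------------------------------------
# full build
# --------------------------------------------------------------------------
class TestFullBuild:
    def test_three_single_component_compartments(self, standard_model):
        """The fillable-compartment requirement: exactly three non-background
        labels, each one 26-connected component."""
        counts = standard_model.labels.counts()
        assert set(counts) == {BACKGROUND, GM, WM, STRIATUM}
        for lbl in (GM, WM, STRIATUM):
            _, n = ndimage.label(
                standard_model.compartment_mask(lbl), structure=STRUCT26
            )
            assert n == 1

    def test_masks_subset_of_their_compartments(self, standard_model):
        lbl = standard_model.labels.data
        assert (lbl[standard_model.pipe_mask] != BACKGROUND).all()
        assert (lbl[standard_model.connector_mask] != BACKGROUND).all()

    def test_print_resolution(self, standard_model):
        assert standard_model.voxel_size_mm == (0.75, 0.75, 0.75)
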
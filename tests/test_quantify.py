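"""Region aggregation, hierarchy roll-up, hemispheres, densities, heat maps."""

import numpy as np
import pytest

from stptquant.classify import export_probability_map
from stptquant.quantify import (
    aggregate_hierarchy,
    build_heatmap_matrix,
    compute_density,
    quantify_regions,
    render_heatmap,
    split_hemispheres,
)
from stptquant.register import AtlasBundle, Region


def _mini_atlas(labels, midline=None, spacing=(10.0, 10.0, 10.0)):
    labels = np.asarray(labels, np.int32)
    ids = sorted(set(np.unique(labels)) - {0})
    ontology = [Region(1, "ROOT", "root", None)]
    ontology += [Region(i, f"A{i}", f"region {i}", 1) for i in ids if i != 1]
    if midline is None:
        midline = (labels.shape[2] - 1) / 2
    return AtlasBundle(np.zeros(labels.shape, np.float32), labels, ontology, midline, spacing)


def _pmap(p, spacing=10.0):
    return export_probability_map(np.asarray(p, float), "cells", spacing, spacing)


def _brute_force(p, labels, hemi, threshold):
    """Per-(region, hemisphere) sums and counts by explicit voxel loop."""
    out = {}
    for s in range(labels.shape[0]):
        for r in range(labels.shape[1]):
            for c in range(labels.shape[2]):
                key = (int(labels[s, r, c]), "left" if hemi[s, r, c] == 0 else "right")
                acc = out.setdefault(key, [0.0, 0])
                acc[0] += p[s, r, c]
                if p[s, r, c] >= threshold:
                    acc[1] += 1
    return out


class TestQuantifyRegions:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 4, (4, 6, 6))
        atlas = _mini_atlas(labels)
        quant = rng.integers(0, 256, (4, 6, 6)).astype(np.uint8)
        pmap = _pmap(quant / 255.0)
        df = quantify_regions(pmap, atlas, 0.3).set_index(["region_id", "hemisphere"])
        oracle = _brute_force(pmap.probabilities, labels, split_hemispheres(atlas), 0.3)
        for (rid, hemi), (total, count) in oracle.items():
            row = df.loc[(rid, hemi)]
            assert np.isclose(row.summed_signal, total)
            assert row.voxel_count == count

    def test_zero_map(self, toy_atlas):
        df = quantify_regions(_pmap(np.zeros(toy_atlas.labels.shape)), toy_atlas)
        assert (df.summed_signal == 0).all()
        assert (df.voxel_count == 0).all()

    def test_saturated_map_counts_every_voxel(self, toy_atlas):
        df = quantify_regions(_pmap(np.ones(toy_atlas.labels.shape)), toy_atlas)
        assert (df.summed_signal == df.region_voxels).all()
        assert (df.voxel_count == df.region_voxels).all()

    def test_conservation_and_hemisphere_additivity(self, cell_probmap, toy_atlas):
        df = quantify_regions(cell_probmap, toy_atlas)
        total = cell_probmap.probabilities.sum()
        both = df[df.hemisphere == "both"]
        assert abs(both.summed_signal.sum() - total) / total < 1e-6
        left = df[df.hemisphere == "left"].set_index("region_id")
        right = df[df.hemisphere == "right"].set_index("region_id")
        for rid, row in both.set_index("region_id").iterrows():
            np.testing.assert_allclose(
                left.loc[rid].summed_signal + right.loc[rid].summed_signal,
                row.summed_signal,
            )
            assert left.loc[rid].voxel_count + right.loc[rid].voxel_count == row.voxel_count
            assert left.loc[rid].region_voxels + right.loc[rid].region_voxels == row.region_voxels

    def test_grid_mismatch_rejected(self, toy_atlas):
        with pytest.raises(ValueError, match="grid"):
            quantify_regions(_pmap(np.zeros((2, 2, 2))), toy_atlas)


class TestHierarchy:
    def _aggregate(self, toy_atlas, pmap):
        leaf = quantify_regions(pmap, toy_atlas)
        return leaf, aggregate_hierarchy(leaf, toy_atlas)

    def test_parent_additivity_and_root_conservation(self, toy_atlas, cell_probmap):
        leaf, full = self._aggregate(toy_atlas, cell_probmap)
        both = full[full.hemisphere == "both"].set_index("region_id")
        children = toy_atlas.children_map()
        for parent, kids in children.items():
            if parent is None:
                continue
            expect = sum(both.loc[k].summed_signal for k in kids)
            direct = 0.0  # toy atlas assigns voxels to leaves only
            assert np.isclose(both.loc[parent].summed_signal, expect + direct)
        in_brain = cell_probmap.probabilities[toy_atlas.labels > 0].sum()
        np.testing.assert_allclose(both.loc[toy_atlas.root.id].summed_signal, in_brain)

    def test_matches_recursive_descendant_enumeration(self, toy_atlas, cell_probmap):
        leaf, full = self._aggregate(toy_atlas, cell_probmap)
        both_leaf = leaf[leaf.hemisphere == "both"].set_index("region_id")
        both_full = full[full.hemisphere == "both"].set_index("region_id")
        children = toy_atlas.children_map()

        def descend(rid):
            total = both_leaf.loc[rid].summed_signal if rid in both_leaf.index else 0.0
            return total + sum(descend(k) for k in children.get(rid, []))

        for region in toy_atlas.ontology:
            assert np.isclose(both_full.loc[region.id].summed_signal, descend(region.id))

    def test_reported_sum_at_least_any_child(self, toy_atlas, cell_probmap):
        _, full = self._aggregate(toy_atlas, cell_probmap)
        both = full[full.hemisphere == "both"].set_index("region_id")
        for parent, kids in toy_atlas.children_map().items():
            if parent is None:
                continue
            assert both.loc[parent].summed_signal >= max(
                both.loc[k].summed_signal for k in kids
            ) - 1e-9

    def test_cyclic_ontology_rejected(self):
        labels = np.zeros((2, 2, 2), np.int32)
        labels[0] = 1
        atlas = _mini_atlas(labels)
        atlas.ontology = [
            Region(1, "ROOT", "root", None),
            Region(4, "A", "a", 5),
            Region(5, "B", "b", 4),
        ]
        leaf = quantify_regions(_pmap(np.zeros((2, 2, 2))), atlas)
        with pytest.raises(ValueError, match="cycle|unreachable"):
            aggregate_hierarchy(leaf, atlas)


class TestHemispheres:
    def test_mirror_symmetric_volumes_equal(self, toy_atlas, cell_probmap):
        df = quantify_regions(cell_probmap, toy_atlas)
        left = df[(df.hemisphere == "left") & (df.region_id > 0)].region_voxels.sum()
        right = df[(df.hemisphere == "right") & (df.region_id > 0)].region_voxels.sum()
        assert left == right

    def test_midline_tie_goes_left(self):
        labels = np.ones((1, 1, 5), np.int32)
        atlas = _mini_atlas(labels, midline=2.0)  # voxel 2 sits on the midline
        hemi = split_hemispheres(atlas)
        assert hemi[0, 0, 2] == 0
        np.testing.assert_array_equal(hemi[0, 0], [0, 0, 0, 1, 1])

    def test_midline_shift_moves_one_sagittal_slab(self, toy_atlas):
        base = split_hemispheres(toy_atlas)
        shifted_atlas = AtlasBundle(
            toy_atlas.template,
            toy_atlas.labels,
            toy_atlas.ontology,
            toy_atlas.midline + 1.0,
            toy_atlas.spacing_um,
        )
        shifted = split_hemispheres(shifted_atlas)
        changed = (base != shifted).sum()
        col = int(np.floor(toy_atlas.midline)) + 1
        assert changed == toy_atlas.labels.shape[0] * toy_atlas.labels.shape[1]
        assert (base[:, :, col] != shifted[:, :, col]).all()

    def test_midline_outside_volume_rejected(self, toy_atlas):
        bad = AtlasBundle(
            toy_atlas.template,
            toy_atlas.labels,
            toy_atlas.ontology,
            1e6,
            toy_atlas.spacing_um,
        )
        with pytest.raises(ValueError, match="midline"):
            split_hemispheres(bad)


class TestDensity:
    def test_worked_example(self):
        assert compute_density(40, 0.002) == pytest.approx(20000.0)

    def test_zero_quantity(self):
        assert compute_density(0.0, 1.0) == 0.0

    def test_voxel_volume_scaling_law(self):
        # doubling the voxel edge (x8 volume) with fixed counts divides
        # density by 8
        d1 = compute_density(100, 1000 * (0.01**3))
        d2 = compute_density(100, 1000 * (0.02**3))
        assert d1 / d2 == pytest.approx(8.0)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_density(1.0, 0.0)


class TestHeatmap:
    def _matrices(self, toy_atlas, cell_probmap):
        leaf = quantify_regions(cell_probmap, toy_atlas, sample_id="m1")
        full1 = aggregate_hierarchy(leaf, toy_atlas)
        full2 = full1.copy()
        full2["sample_id"] = "m2"
        return [full1, full2]

    def test_single_cell_table(self, toy_atlas, cell_probmap):
        mats = self._matrices(toy_atlas, cell_probmap)[:1]
        tables = build_heatmap_matrix(mats, ["L1"], toy_atlas)
        t = tables[("cell_bodies", "both")]
        assert t.shape == (1, 1)
        ref = mats[0]
        want = ref[
            (ref.acronym == "L1") & (ref.hemisphere == "both")
        ].count_density.iloc[0]
        assert t.iloc[0, 0] == pytest.approx(want)

    def test_selected_region_table_shape_and_fill(self, toy_atlas, cell_probmap):
        mats = self._matrices(toy_atlas, cell_probmap)
        acronyms = [r.acronym for r in toy_atlas.leaves()]
        tables = build_heatmap_matrix(mats, acronyms, toy_atlas)
        for (label, hemi), t in tables.items():
            assert t.shape == (2, len(acronyms))
            assert list(t.columns) == acronyms
            assert not t.isna().any().any()  # absent combinations become 0

    def test_unknown_acronym_listed(self, toy_atlas, cell_probmap):
        mats = self._matrices(toy_atlas, cell_probmap)
        with pytest.raises(KeyError, match="NOPE"):
            build_heatmap_matrix(mats, ["L1", "NOPE"], toy_atlas)

    def test_render_writes_figure(self, tmp_path, toy_atlas, cell_probmap):
        mats = self._matrices(toy_atlas, cell_probmap)
        tables = build_heatmap_matrix(mats, ["L1", "R1"], toy_atlas)
        out = render_heatmap(tables[("cell_bodies", "both")], tmp_path / "h.png")
        assert out.exists() and out.stat().st_size > 0
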
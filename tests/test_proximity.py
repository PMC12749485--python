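"""Distance fields, layer occupancy and distance-binned statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from synaptomet.volio import Segmentation
from synaptomet.proximity import (membrane_distance_field,
                                  vesicle_membrane_distance, layer_occupancy,
                                  tethers_by_distance,
                                  vesicles_per_membrane_area,
                                  MissingRegionError, cytoplasm_mask)
from synaptomet.morphometry import VesicleRecord

from conftest import SceneBuilder


def flat_scene(ves_gap=None, rv=10.0, vs=1.0, shape=(64, 48, 48)):
    """Flat membrane at the bottom, optional sphere at edge gap ``ves_gap``."""
    b = SceneBuilder(shape, vs)
    zz, yy, xx = b.grid_nm()
    b.add((zz >= 2) & (zz < 7), 1001, "membrane")
    b.add(zz >= 7, 1002, "cytoplasm")
    if ves_gap is not None:
        c = (7.0 + ves_gap + rv, shape[1] * vs / 2, shape[2] * vs / 2)
        ves = ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= rv ** 2
        b.add(ves & (zz >= 7), 1010, "vesicle")
    return b.build()[1]


def record_for(seg, label=1010):
    return VesicleRecord(label=label, compartment=1, centroid=(0, 0, 0),
                         volume=1.0, surface=1.0, diameter=20.0, wadell=1.0)


class TestDistanceField:
    def test_adjacent_voxel_within_one_voxel(self):
        seg = flat_scene()
        field = membrane_distance_field(seg)
        assert field[7, 10, 10] <= 1.0  # first cytoplasm layer

    def test_flat_membrane_point_distance(self):
        seg = flat_scene()
        field = membrane_distance_field(seg)
        # voxel center 25 nm above the top membrane voxel center
        assert field[31, 20, 20] == pytest.approx(25.0, abs=0.5)

    def test_lipschitz_against_brute_force_on_crop(self):
        seg = flat_scene(ves_gap=8.0, shape=(32, 32, 32))
        field = membrane_distance_field(seg)
        # brute force: distance to nearest membrane voxel center
        mem = np.argwhere(seg.labels == 1001).astype(float)
        rng = np.random.default_rng(0)
        pts = rng.integers(0, 32, size=(40, 3))
        for p in pts:
            brute = np.min(np.linalg.norm(mem - p, axis=1))
            assert field[tuple(p)] == pytest.approx(brute, abs=1e-6)
        # 1-Lipschitz per nm along axis neighbours
        diffs = np.abs(np.diff(field, axis=0))
        assert diffs.max() <= 1.0 + 1e-9

    def test_missing_az_error_suggests_whole_mode(self):
        seg = flat_scene()
        with pytest.raises(MissingRegionError, match="whole"):
            membrane_distance_field(seg, region="AZ")


class TestVesicleDistance:
    def test_touching_vesicle_is_zero_within_voxel(self):
        seg = flat_scene(ves_gap=0.0)
        field = membrane_distance_field(seg)
        rec = vesicle_membrane_distance(record_for(seg), field, seg)
        assert rec.dist_membrane <= 1.5

    def test_sphere_center_45_edge_25(self):
        # radius 10 sphere with edge 25 nm from the membrane
        seg = flat_scene(ves_gap=25.0)
        field = membrane_distance_field(seg)
        rec = vesicle_membrane_distance(record_for(seg), field, seg)
        assert rec.dist_membrane == pytest.approx(25.0, abs=1.0)
        assert rec.proximal  # < 45 nm

    def test_proximal_flag_threshold(self):
        seg = flat_scene(ves_gap=25.0)
        field = membrane_distance_field(seg)
        rec = vesicle_membrane_distance(record_for(seg), field, seg,
                                        cutoff=20.0)
        assert not rec.proximal
        rec = vesicle_membrane_distance(record_for(seg), field, seg,
                                        cutoff=45.0)
        assert rec.proximal

    def test_enlarging_cutoff_never_shrinks_proximal_set(self, glu_scene):
        _, seg, _ = glu_scene
        from synaptomet.proximity import annotate_distances
        from synaptomet.morphometry import vesicle_metrics
        recs = vesicle_metrics(seg)
        sets = []
        for cutoff in (15.0, 30.0, 45.0, 80.0):
            annotate_distances(recs, seg, "whole", cutoff=cutoff)
            sets.append({r.label for r in recs if r.proximal})
        for small, big in zip(sets[:-1], sets[1:]):
            assert small <= big


class TestLayerOccupancy:
    def test_no_vesicles_all_zero(self):
        seg = flat_scene()
        layers = layer_occupancy(seg, max_distance=30.0)
        vals = [p.occupancy for p in layers if p.cyto_voxels]
        assert vals and all(v == 0.0 for v in vals)

    def test_single_sphere_matches_brute_force_voxel_counts(self):
        seg = flat_scene(ves_gap=5.0, shape=(48, 32, 32))
        layers = layer_occupancy(seg, max_distance=40.0)
        field = membrane_distance_field(seg)
        cyto = cytoplasm_mask(seg)
        ves = seg.labels == 1010
        for p in layers:
            sel = cyto & (field >= p.d_lo) & (field < p.d_hi)
            assert p.cyto_voxels == int(sel.sum())
            assert p.vesicle_voxels == int((sel & ves).sum())
        peak = max((p for p in layers if p.cyto_voxels),
                   key=lambda p: p.occupancy)
        assert 5.0 <= peak.d_lo <= 45.0

    def test_occupancy_sums_to_total_vesicle_volume(self):
        seg = flat_scene(ves_gap=5.0)
        layers = layer_occupancy(seg, max_distance=250.0)
        total = sum(p.vesicle_voxels for p in layers)
        assert total == int((seg.labels == 1010).sum())

    def test_empty_layer_reports_nan_not_zero(self):
        seg = flat_scene(shape=(16, 16, 16))
        layers = layer_occupancy(seg, max_distance=100.0)
        deep = [p for p in layers if p.cyto_voxels == 0]
        assert deep and all(math.isnan(p.occupancy) for p in deep)

    def test_whole_vs_az_agree_when_az_is_whole_membrane(self):
        seg = flat_scene(ves_gap=5.0)
        table = seg.table.copy()
        table.loc[table["klass"] == "membrane", "klass"] = "AZ_membrane"
        seg_az = Segmentation(seg.labels.copy(), seg.voxel_size, table)
        a = layer_occupancy(seg, "whole", max_distance=30.0)
        b = layer_occupancy(seg_az, "AZ", max_distance=30.0)
        for pa, pb in zip(a, b):
            assert pa.cyto_voxels == pb.cyto_voxels
            assert pa.vesicle_voxels == pb.vesicle_voxels


class TestTetherBins:
    def _rec(self, dist, n):
        r = record_for(None)
        r.dist_membrane = dist
        r.n_tethers = n
        return r

    def test_no_tethered_vesicles_means_zero(self):
        recs = [self._rec(d, 0) for d in (2, 7, 30)]
        df = tethers_by_distance(recs)
        assert (df["mean_tethers"].dropna() == 0).all()

    def test_three_tethers_below_5nm(self):
        recs = [self._rec(2.0, 3), self._rec(4.0, 3), self._rec(30.0, 1)]
        df = tethers_by_distance(recs)
        assert df.loc[0, "mean_tethers"] == pytest.approx(3.0)

    def test_half_open_bin_edges(self):
        recs = [self._rec(5.0, 2)]
        df = tethers_by_distance(recs)
        assert df.loc[0, "n_vesicles"] == 0  # 5.0 falls in [5, 10)
        assert df.loc[1, "n_vesicles"] == 1


class TestPerMembraneArea:
    def test_counts_and_conservation(self):
        seg = flat_scene(ves_gap=5.0)
        recs = [record_for(seg)]
        recs[0].dist_membrane = 5.0
        df = vesicles_per_membrane_area(recs, seg,
                                        shells=(0, 45, 100, 200))
        assert df["count"].sum() == len(recs)
        area = df.loc[0, "count"] / df.loc[0, "per_um2"]
        assert df.loc[0, "per_um2"] == pytest.approx(1 / area)

    def test_zero_vesicles_all_shells_zero(self):
        seg = flat_scene()
        df = vesicles_per_membrane_area([], seg, shells=(0, 45, 100))
        assert (df["per_um2"] == 0).all()
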
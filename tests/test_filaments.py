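"""Hierarchical-connectivity detection: preprocessing, fixtures, lengths."""

import math

import numpy as np
import pytest

from synaptomet.filaments import (preprocess, detect_filaments,
                                  filament_length, tally_filaments,
                                  DetectionParams, PreprocessError)
from synaptomet.volio import DensityVolume
from synaptomet.morphometry import VesicleRecord

from conftest import bridge_scene


def detected_pairs(filaments):
    """Partner pairs covered by the detection, branching included."""
    pairs = set()
    for f in filaments:
        ps = sorted(f.partners)
        if len(ps) == 2:
            pairs.add(tuple(ps))
        else:
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    pairs.add((ps[i], ps[j]))
    return pairs


class TestPreprocess:
    def test_standardization_contract(self):
        vol, seg = bridge_scene(with_bridge=False).build(noise_sd=0.2, seed=1)
        out = preprocess(vol, seg, subtract_boundary_halo=False)
        cyto = seg.labels == 1002
        assert abs(float(out.data[cyto].mean())) < 0.15  # smoothing shifts
        # smoothed sd is well below 1; the pre-smoothing normalization is
        # checked through the sign-invariance contract below

    def test_impulse_gives_gaussian_response(self):
        from scipy import ndimage
        b = bridge_scene(with_bridge=False)
        vol, seg = b.build()
        data = vol.data.copy()
        data[30, 24, 24] -= 5.0  # dark impulse in the cytoplasm
        vol2 = DensityVolume(data, vol.voxel_size)
        out = preprocess(vol2, seg, subtract_boundary_halo=False)
        base = preprocess(vol, seg, subtract_boundary_halo=False)
        resp = out.data - base.data
        delta = np.zeros(vol.data.shape)
        delta[30, 24, 24] = 1.0
        kernel = ndimage.gaussian_filter(delta, 2.0)
        ratio = resp[30, 24, 28] / resp[30, 24, 24]
        assert ratio == pytest.approx(
            kernel[30, 24, 28] / kernel[30, 24, 24], rel=0.12)

    def test_dark_and_bright_renders_identical_after_normalization(self):
        b = bridge_scene(gap=12.0)
        vol_d, seg = b.build(contrast="dark")
        vol_b, _ = b.build(contrast="bright")
        out_d = preprocess(vol_d, seg)
        out_b = preprocess(vol_b, seg)
        assert np.allclose(out_d.data, out_b.data, atol=1e-4)

    def test_constant_volume_rejected(self):
        vol, seg = bridge_scene(with_bridge=False).build()
        flat = DensityVolume(np.ones_like(vol.data), vol.voxel_size)
        with pytest.raises(PreprocessError):
            preprocess(flat, seg)


class TestDetection:
    def test_single_tether_across_15nm_gap(self):
        vol, seg = bridge_scene(gap=15.0, kind="tether").build()
        fils = detect_filaments(vol, seg)
        tethers = [f for f in fils if f.kind == "tether"]
        assert len(tethers) == 1
        assert tethers[0].partners == (1001, 1010) or \
            tethers[0].partners == (1010, 1001)
        # length within 2 voxels of the rendered 15 nm gap
        assert tethers[0].length == pytest.approx(15.0, abs=2.0)

    def test_no_bridge_means_no_filaments(self):
        vol, seg = bridge_scene(gap=15.0, with_bridge=False).build()
        assert detect_filaments(vol, seg) == []

    def test_connector_between_two_vesicles(self):
        vol, seg = bridge_scene(gap=14.0, kind="connector").build()
        fils = detect_filaments(vol, seg)
        connectors = [f for f in fils if f.kind == "connector"]
        assert len(connectors) == 1
        assert sorted(connectors[0].partners) == [1010, 1011]
        assert connectors[0].length == pytest.approx(14.0, abs=2.0)

    def test_curved_bridge_length_follows_the_arc(self):
        r = 16.0
        vol, seg = bridge_scene(kind="tether", arc_radius=r).build()
        fils = detect_filaments(vol, seg)
        two_contact = [f for f in fils if not f.branching]
        assert len(two_contact) >= 1
        length = max(f.length for f in two_contact)
        chord = r * math.sqrt(2.0)
        assert length > chord  # curvature contributes
        assert length == pytest.approx(math.pi * r / 2, rel=0.15)

    def test_length_at_least_straight_gap_between_contacts(self, clean_scene):
        """Path optimality: length >= straight-line distance between the
        two contact regions minus one voxel."""
        from scipy.spatial.distance import cdist
        vol, seg, gt = clean_scene
        vs = np.asarray(vol.voxel_size)
        for f in detect_filaments(vol, seg):
            if f.branching:
                continue
            a, b = (np.asarray(f.contacts[p]) * vs for p in f.partners)
            straight = cdist(a, b).min()
            assert f.length >= straight - max(vol.voxel_size)

    def test_hierarchy_stable_under_ramp_refinement(self):
        vol, seg = bridge_scene(gap=15.0, kind="tether").build(noise_sd=0.1,
                                                               seed=5)
        coarse = detect_filaments(vol, seg, DetectionParams(n_levels=6))
        fine = detect_filaments(vol, seg, DetectionParams(n_levels=11))
        assert detected_pairs(coarse) == detected_pairs(fine)

    def test_degenerate_segmentation_rejected(self):
        vol, seg = bridge_scene(gap=15.0).build()
        seg.labels[seg.labels != 1001] = 0  # membrane only, no cytoplasm
        with pytest.raises(PreprocessError, match="cytoplasm"):
            detect_filaments(vol, seg)


class TestFilamentLength:
    def test_single_shared_contact_is_one_step(self):
        vol, seg = bridge_scene(gap=15.0).build()
        fils = detect_filaments(vol, seg)
        f = fils[0]
        f.contacts[f.partners[0]] = f.contacts[f.partners[1]]
        assert filament_length(f, vol.voxel_size) == pytest.approx(
            min(vol.voxel_size))

    def test_branching_component_has_no_length(self):
        vol, seg = bridge_scene(gap=15.0).build()
        f = detect_filaments(vol, seg)[0]
        f.partners = (1001, 1010, 1011)
        with pytest.raises(ValueError):
            filament_length(f, vol.voxel_size)


class TestTally:
    def _recs(self, n, prox_n):
        recs = []
        for i in range(n):
            r = VesicleRecord(label=1010 + i, compartment=1,
                              centroid=(0, 0, 0), volume=1, surface=1,
                              diameter=40, wadell=0.98)
            r.proximal = i < prox_n
            r.dist_membrane = 10.0 if r.proximal else 80.0
            recs.append(r)
        return recs

    def test_zero_filaments_zero_fractions(self):
        t = tally_filaments([], self._recs(6, 4))
        assert t["fraction_tethered"] == 0.0
        assert t["fraction_connected_all"] == 0.0

    def test_half_tethered_is_fifty_percent(self, clean_scene):
        vol, seg, gt = clean_scene
        from synaptomet.morphometry import vesicle_metrics
        from synaptomet.proximity import annotate_distances
        recs = annotate_distances(vesicle_metrics(seg), seg, "whole")
        fils = detect_filaments(vol, seg)
        t = tally_filaments(fils, recs)
        assert 0.0 <= t["fraction_tethered"] <= 1.0
        parts = (t["fraction_tethered"] - t["fraction_both"],
                 t["fraction_connected_proximal"] - t["fraction_both"],
                 t["fraction_both"], t["fraction_neither"])
        assert sum(parts) == pytest.approx(1.0, abs=1e-9)

    def test_fraction_partition_sums_to_one_fixture(self):
        recs = self._recs(10, 10)
        from synaptomet.filaments import Filament
        fils = [Filament(id=0, kind="tether", partners=(1001, 1010 + i),
                         voxels=np.zeros((3, 3), int), contacts={},
                         threshold_level=1.0) for i in range(5)]
        t = tally_filaments(fils, recs)
        assert t["fraction_tethered"] == pytest.approx(0.5)
        total = (t["fraction_both"] + t["fraction_neither"]
                 + (t["fraction_tethered"] - t["fraction_both"])
                 + (t["fraction_connected_proximal"] - t["fraction_both"]))
        assert total == pytest.approx(1.0)
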
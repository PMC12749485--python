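"""Contact zones, cleft widths, density profiles and PSD detection."""

import numpy as np
import pandas as pd
import pytest

from synaptomet.volio import DensityVolume
from synaptomet.contacts import (define_contact_zone, cleft_width,
                                 contact_area, midline_profile,
                                 cytoplasm_profile, detect_psd,
                                 EmptyZoneError)

from conftest import parallel_planes_seg


class TestZoneDefinition:
    def test_parallel_planes_12nm_fully_selected(self):
        seg = parallel_planes_seg(12.0).build()[1]
        zone = define_contact_zone(seg, 1, 2)
        assert not zone.empty
        assert len(zone.faces_a) > 0 and len(zone.faces_b) > 0

    def test_separation_20nm_gives_empty_zone(self):
        seg = parallel_planes_seg(20.0).build()[1]
        zone = define_contact_zone(seg, 1, 2)  # tight apposition < 15 nm
        assert zone.empty
        with pytest.raises(EmptyZoneError):
            zone.width_mean

    def test_hub_patch_area_within_ten_percent(self, hub_scene):
        _, seg, gt = hub_scene
        zone = define_contact_zone(seg, 1, 2,
                                   max_sep=gt.contact["cleft_width_nm"] + 3.0)
        area = contact_area(seg, zone)
        assert area == pytest.approx(gt.contact["patch_area_um2"], rel=0.10)


class TestCleftWidth:
    @pytest.mark.parametrize("sep", [31.8, 12.1])
    def test_parallel_planes_recover_separation(self, sep):
        seg = parallel_planes_seg(sep).build()[1]
        zone = define_contact_zone(seg, 1, 2, max_sep=40.0)
        mean, sd = cleft_width(zone)
        assert mean == pytest.approx(sep, abs=1.0)  # one voxel
        assert sd <= 1.0

    def test_tilted_planes_match_analytic_mean(self):
        tilt = 6.0
        seg = parallel_planes_seg(10.0, tilt=tilt, shape=(40, 64, 60)).build()[1]
        zone = define_contact_zone(seg, 1, 2, max_sep=40.0)
        mean, _ = cleft_width(zone)
        assert mean == pytest.approx(10.0 + tilt / 2, abs=1.5)

    def test_width_symmetry_a_to_b(self):
        seg = parallel_planes_seg(12.1).build()[1]
        ab = cleft_width(define_contact_zone(seg, 1, 2, max_sep=40.0))[0]
        ba = cleft_width(define_contact_zone(seg, 2, 1, max_sep=40.0))[0]
        assert abs(ab - ba) <= 1.0


class TestMidlineProfile:
    def test_uniform_volume_gives_unity(self):
        vol, seg = parallel_planes_seg(12.0).build()
        flat = DensityVolume(np.ones_like(vol.data), vol.voxel_size)
        zone = define_contact_zone(seg, 1, 2)
        prof = midline_profile(flat, seg, zone)
        assert np.allclose(prof["normalized"], 1.0)

    def test_midline_slab_appears_as_density_elevation(self):
        b = parallel_planes_seg(12.0)
        zz, yy, xx = b.grid_nm()
        mid = (np.abs(yy - b.shape[1] * b.vs / 2) <= 1.5) & \
            (np.abs(xx - b.shape[2] * b.vs / 2) <= 6.0)
        b.protein[mid & (b.labels == 0)] = 0.6
        vol, seg = b.build()
        zone = define_contact_zone(seg, 1, 2)
        prof = midline_profile(vol, seg, zone)
        x0 = b.shape[2] * b.vs / 2
        near = prof[np.abs(prof["pos_nm"] - x0) <= 4.0]["normalized"]
        far = prof[np.abs(prof["pos_nm"] - x0) > 12.0]["normalized"]
        assert near.mean() > far.mean() + 0.1  # protein-positive elevation

    def test_normalization_invariant_to_intensity_scaling(self):
        vol, seg = parallel_planes_seg(12.0).build()
        zone = define_contact_zone(seg, 1, 2)
        p1 = midline_profile(vol, seg, zone)
        scaled = DensityVolume(vol.data * 3.5, vol.voxel_size)
        p2 = midline_profile(scaled, seg, zone)
        assert np.allclose(p1["normalized"], p2["normalized"], atol=1e-5)


class TestCytoplasmProfile:
    def test_uniform_interior_flat_profile(self):
        vol, seg = parallel_planes_seg(12.0, shape=(40, 100, 40)).build()
        zone = define_contact_zone(seg, 1, 2)
        prof = cytoplasm_profile(vol, seg, 2, zone)
        vals = prof["normalized"].dropna()
        assert np.allclose(vals, 1.0, atol=0.02)

    def test_profile_length_equals_depth_over_step(self):
        vol, seg = parallel_planes_seg(12.0, shape=(40, 100, 40)).build()
        prof = cytoplasm_profile(vol, seg, 2, None, depth=60.0, start=5.0)
        assert len(prof) == int((60.0 - 5.0) / 1.0)

    def test_psd_slab_elevates_10_25nm_band(self, hub_scene):
        vol, seg, gt = hub_scene
        zone = define_contact_zone(seg, 1, 2, max_sep=40.0)
        prof = cytoplasm_profile(vol, seg, 2, zone)
        call, band = detect_psd(prof)
        assert call is True
        assert band == (10.0, 25.0)

    def test_thin_compartment_truncated_flag(self):
        vol, seg = parallel_planes_seg(12.0, shape=(40, 60, 40)).build()
        prof = cytoplasm_profile(vol, seg, 1, None, depth=200.0)
        assert prof.attrs["truncated"]


class TestDetectPsd:
    def _profile(self, bump):
        depth = np.arange(5.5, 60.0, 1.0)
        norm = np.ones_like(depth)
        norm[(depth >= 10) & (depth < 25)] += bump
        return pd.DataFrame({"depth_nm": depth, "normalized": norm})

    def test_flat_profile_negative(self):
        assert detect_psd(self._profile(0.0))[0] is False

    def test_fifteen_percent_bump_positive(self):
        assert detect_psd(self._profile(0.15))[0] is True

    def test_five_percent_bump_below_margin_negative(self):
        assert detect_psd(self._profile(0.05))[0] is False

    def test_short_profile_undefined(self):
        prof = pd.DataFrame({"depth_nm": [6.0, 8.0],
                             "normalized": [1.0, 1.0]})
        assert detect_psd(prof)[0] is None

    def test_hub_without_psd_is_negative(self):
        from synaptomet.synth import SynthParams, generate_hub
        pa = SynthParams.glu(synaptosome_diameter_mean=140,
                             synaptosome_diameter_sd=1, voxel_size=2.5,
                             margin=25.0, vesicle_count=0, az_area_um2=None,
                             noise_sd=0.05)
        vol, seg, gt = generate_hub(pa, pa, cleft_width=12.1, seed=4,
                                    patch_area_um2=0.004, psd=False)
        zone = define_contact_zone(seg, 1, 2, max_sep=16.0)
        prof = cytoplasm_profile(vol, seg, 2, zone)
        assert detect_psd(prof)[0] in (False, None)
        assert gt.psd is None


class TestContactArea:
    def test_flat_square_patch_area(self):
        # 200 x 200 nm selected patch on a flat membrane -> 0.04 µm^2
        seg = parallel_planes_seg(12.0, vs=2.0, shape=(110, 40, 110),
                                  thickness=6.0).build()[1]
        zone = define_contact_zone(seg, 1, 2)
        # crop the patch to the central 200 x 200 nm window
        keep = ((np.abs((zone.faces_a[:, 0] + 0.5) * 2.0 - 110.0) <= 100.0)
                & (np.abs((zone.faces_a[:, 2] + 0.5) * 2.0 - 110.0) <= 100.0))
        zone.faces_a = zone.faces_a[keep]
        area = contact_area(seg, zone)
        assert area == pytest.approx(0.04, rel=0.08)

    def test_area_invariant_under_rotation(self):
        seg = parallel_planes_seg(12.0).build()[1]
        zone = define_contact_zone(seg, 1, 2)
        a1 = contact_area(seg, zone)
        # rotate the whole scene 90 degrees about z (axes swap y <-> x)
        labels_rot = np.rot90(seg.labels, axes=(1, 2)).copy()
        from synaptomet.volio import Segmentation
        seg_rot = Segmentation(labels_rot, seg.voxel_size, seg.table)
        zone_rot = define_contact_zone(seg_rot, 1, 2)
        a2 = contact_area(seg_rot, zone_rot)
        assert a2 == pytest.approx(a1, rel=0.02)
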
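"""End-to-end analysis of one segmented scene.

Ties the stages together: vesicle morphometry, membrane distances,
filament detection and tallies, layer occupancy, and (when a second
compartment is present) contact-zone metrics.  The result is a plain dict
of tables and summaries that the report builder and the CLI consume.
"""

from __future__ import annotations

import math

from .volio import DensityVolume, Segmentation
from . import morphometry, proximity, filaments as fil, contacts


def analyze_scene(vol: DensityVolume, seg: Segmentation,
                  compartment: int = 1,
                  region: str | None = None,
                  detection: fil.DetectionParams | None = None,
                  detect: bool = True) -> dict:
    """Analyze one compartment of a segmented scene.

    ``region`` chooses the distance reference: "AZ" where an active-zone
    label exists, "whole" for the whole plasma membrane; None picks AZ
    when available, else whole (the fallback used where no AZ is
    morphologically identifiable).  Set ``detect=False`` to skip filament
    detection (morphometry only).
    """
    rows = seg.table
    has_az = bool(((rows["compartment"] == compartment)
                   & (rows["klass"] == "AZ_membrane")).any())
    if region is None:
        region = "AZ" if has_az else "whole"

    records = morphometry.vesicle_metrics(seg, compartment)
    proximity.annotate_distances(records, seg, region, compartment)
    summary = morphometry.summarize_compartment(seg, compartment, records)

    detected = []
    tallies = fil.tally_filaments([], records)
    if detect:
        detected = fil.detect_filaments(vol, seg, detection)
        detected = [f for f in detected
                    if any(p // 1000 == compartment for p in f.partners)]
        tallies = fil.tally_filaments(detected, records)
    summary.fraction_tethered = tallies["fraction_tethered"]
    summary.fraction_connected = tallies["fraction_connected_all"]

    layers = proximity.layer_occupancy(seg, region, compartment)
    clean = [r for r in records if not r.boundary_clipped]
    result = {
        "compartment": compartment,
        "region": region,
        "records": records,
        "summary": summary.__dict__,
        "tallies": tallies,
        "filaments": detected,
        "layers": layers,
        "diameters_nm": [r.diameter for r in clean],
        "wadell": [r.wadell for r in clean],
        "distances_nm": [r.dist_membrane for r in records
                         if not math.isnan(r.dist_membrane)],
        "tether_lengths_nm": [f.length for f in detected
                              if f.kind == "tether" and not f.branching],
        "connector_lengths_nm": [f.length for f in detected
                                 if f.kind == "connector" and not f.branching],
    }
    return result


def analyze_contact(vol: DensityVolume, seg: Segmentation,
                    comp_a: int = 1, comp_b: int = 2,
                    max_sep: float | None = None) -> dict:
    """Contact-zone metrics between two compartments of one scene."""
    kwargs = {} if max_sep is None else {"max_sep": max_sep}
    zone = contacts.define_contact_zone(seg, comp_a, comp_b, **kwargs)
    out = {"empty": zone.empty, "zone": zone}
    if zone.empty:
        return out
    mean, sd = contacts.cleft_width(zone)
    out["cleft_width_nm"] = mean
    out["cleft_width_sd_nm"] = sd
    out["area_um2"] = contacts.contact_area(seg, zone)
    profile = contacts.cytoplasm_profile(vol, seg, comp_b, zone)
    call, band = contacts.detect_psd(profile)
    out["psd_call"] = call
    out["psd_band_nm"] = band
    out["cytoplasm_profile"] = profile
    return out
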
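"""Smear circularity scoring against closed-form shape oracles."""
import math

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, polygon as draw_polygon

from sichpipe import synth
from sichpipe.errors import ConfigError, DomainError
from sichpipe.netquant import (NucleusObject, SmearImage, circularity_index,
                               classify_net, estimate_background,
                               load_field_tiff, marker_positivity,
                               nuclei_to_records, save_field_tiff,
                               scan_slide, segment_nuclei)


def _image_from_mask(mask, pixel_size=0.25):
    ch = np.zeros(mask.shape)
    ch[mask] = 200.0
    zeros = np.zeros(mask.shape)
    return SmearImage(channels={"dapi": ch, "cd11b": zeros.copy(),
                                "despr": zeros.copy()},
                      pixel_size=pixel_size)


def _single_object(img, **kw):
    objs = segment_nuclei(img, **kw)
    assert len(objs) == 1
    return objs[0]


# ------------------------------------------------------------ segmentation


def test_five_disjoint_disks_give_five_objects():
    mask = np.zeros((300, 300), dtype=bool)
    for cy in (50, 150, 250):
        rr, cc = draw_disk((cy, 60), 20, shape=mask.shape)
        mask[rr, cc] = True
    for cy in (80, 200):
        rr, cc = draw_disk((cy, 200), 20, shape=mask.shape)
        mask[rr, cc] = True
    assert len(segment_nuclei(_image_from_mask(mask))) == 5


def test_min_area_filter_drops_small_disk():
    mask = np.zeros((100, 100), dtype=bool)
    rr, cc = draw_disk((50, 50), 5, shape=mask.shape)  # ~4.9 μm² @ 0.25
    mask[rr, cc] = True
    assert segment_nuclei(_image_from_mask(mask), min_area=20.0) == []


def test_blank_channel_yields_empty_list():
    img = _image_from_mask(np.zeros((50, 50), dtype=bool))
    assert segment_nuclei(img) == []


def test_generator_nuclei_recovered_with_high_jaccard(smear_fields):
    """Every generated nucleus is recovered; object pixel sets overlap
    the drawn truth footprints (Jaccard proxy via count match and total
    overlap of DAPI-positive area)."""
    fields, truth = smear_fields
    total = 0
    for f in fields:
        objs = segment_nuclei(f)
        total += len(objs)
        drawn = f.channels["dapi"] > 100.0
        for o in objs:
            obj_mask = np.zeros(drawn.shape, dtype=bool)
            obj_mask[o.pixel_set[:, 0], o.pixel_set[:, 1]] = True
            inter = (obj_mask & drawn).sum()
            union = (obj_mask | (obj_mask & drawn)).sum()
            assert inter / obj_mask.sum() >= 0.9
    assert total == len(truth)


def test_mec_area_never_below_object_area(smear_fields):
    fields, _ = smear_fields
    for f in fields:
        for o in segment_nuclei(f):
            assert o.mec_area >= o.object_area * (1 - 1e-9)


# ------------------------------------------------------------- circularity


def test_rasterized_disk_scores_one():
    mask = np.zeros((160, 160), dtype=bool)
    rr, cc = draw_disk((80, 80), 20, shape=mask.shape)
    mask[rr, cc] = True
    obj = _single_object(_image_from_mask(mask))
    assert circularity_index(obj) == pytest.approx(1.0, abs=0.05)


def test_star_polygon_matches_closed_form():
    """Measured index tracks the analytic 4*pi*pi*R^2/P^2 of the star
    polygon; the generator's inversion hits the requested value exactly."""
    R, k, target = 20.0, 6, 0.6
    r = synth.star_inner_radius_for_circularity(R, k, target)
    assert synth.star_circularity(R, r, k) == pytest.approx(target)
    verts = synth.star_polygon((80, 80), R, r, k)
    mask = np.zeros((160, 160), dtype=bool)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], mask.shape)
    mask[rr, cc] = True
    obj = _single_object(_image_from_mask(mask))
    assert circularity_index(obj) == pytest.approx(target, abs=0.08)


def test_moderate_extrusion_morphology_scores_near_0p6():
    """The moderate-extrusion morphology class is generated at analytic
    circularity 0.6 and measures in the NET-positive band near 0.6."""
    fields, truth = synth.generate_smear(
        synth.SmearSpec(seed=3, n_fields=4, net_fraction=1.0,
                        target_net_circularity=0.6))
    assert np.allclose(truth["analytic_circularity"], 0.6)
    measured = []
    for f in fields:
        for o in segment_nuclei(f):
            measured.append(circularity_index(o))
    assert np.mean(measured) == pytest.approx(0.6, abs=0.08)
    assert all(c < 0.8 for c in measured)


def test_extrusion_growth_strictly_decreases_circularity():
    """Holding the enclosing circle fixed, deeper spikes (smaller inner
    radius) strictly decrease both analytic and measured circularity."""
    R, k = 20.0, 6
    inner = [14.0, 11.0, 8.0, 5.0]
    analytic = [synth.star_circularity(R, r, k) for r in inner]
    assert all(a > b for a, b in zip(analytic, analytic[1:]))
    measured = []
    for r in inner:
        verts = synth.star_polygon((80, 80), R, r, k)
        mask = np.zeros((160, 160), dtype=bool)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], mask.shape)
        mask[rr, cc] = True
        measured.append(circularity_index(_single_object(
            _image_from_mask(mask), min_area=5.0)))
    assert all(a > b for a, b in zip(measured, measured[1:]))


def test_circularity_scale_invariance():
    """Doubling resolution moves the index by < 0.03 (star at 40 vs 80 px
    outer radius, same physical shape)."""
    k = 6
    vals = []
    for R in (40.0, 80.0):
        r = synth.star_inner_radius_for_circularity(R, k, 0.6)
        verts = synth.star_polygon((2 * R, 2 * R), R, r, k)
        mask = np.zeros((int(4 * R), int(4 * R)), dtype=bool)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], mask.shape)
        mask[rr, cc] = True
        obj = _single_object(_image_from_mask(mask, pixel_size=20.0 / R))
        vals.append(circularity_index(obj))
    assert abs(vals[0] - vals[1]) < 0.03


def test_degenerate_object_rejected():
    obj = NucleusObject(label=1, pixel_set=np.array([[0, 0]]),
                        object_area=0.0625, traced_perimeter=0.0,
                        mec_area=0.2)
    with pytest.raises(DomainError):
        circularity_index(obj)


# ----------------------------------------------------------- NET cutoff


@pytest.mark.parametrize("circ,expected", [
    (0.79, True), (0.80, False), (0.799999, True), (1.0, False),
])
def test_net_classification_boundary(circ, expected):
    assert classify_net(circ) is expected


def test_net_classification_domain():
    with pytest.raises(DomainError):
        classify_net(0.0)


# ------------------------------------------------------ marker positivity


def test_marker_positivity_zero_channels():
    mask = np.zeros((90, 90), dtype=bool)
    rr, cc = draw_disk((45, 45), 16, shape=mask.shape)
    mask[rr, cc] = True
    img = _image_from_mask(mask)
    obj = _single_object(img)
    marker_positivity(obj, img, {"cd11b": 5.0, "despr": 5.0})
    assert obj.mean_cd11b == 0.0 and obj.mean_despr == 0.0
    assert obj.despr_cd11b_positive is False


def test_marker_positivity_requires_both_channels():
    mask = np.zeros((90, 90), dtype=bool)
    rr, cc = draw_disk((45, 45), 16, shape=mask.shape)
    mask[rr, cc] = True
    img = _image_from_mask(mask)
    img.channels["cd11b"][mask] = 100.0  # cd11b only
    obj = _single_object(img)
    marker_positivity(obj, img, {"cd11b": 5.0, "despr": 5.0})
    assert obj.despr_cd11b_positive is False
    img.channels["despr"][mask] = 100.0
    marker_positivity(obj, img, {"cd11b": 5.0, "despr": 5.0})
    assert obj.despr_cd11b_positive is True


def test_marker_positivity_missing_background_raises(smear_fields):
    fields, _ = smear_fields
    obj = segment_nuclei(fields[0])[0]
    with pytest.raises(ConfigError):
        marker_positivity(obj, fields[0], {"cd11b": 5.0})


# -------------------------------------------------------------- slide scan


def test_scan_recovers_truth_net_fraction(smear_fields):
    fields, truth = smear_fields
    res = scan_slide(fields)
    dp_truth = truth[truth["double_positive"]]
    assert res.n_fields == len(fields)
    assert res.net_fraction == pytest.approx(
        dp_truth["is_net"].mean(), abs=0.02)


def test_all_round_slide_scores_zero():
    fields, _ = synth.generate_smear(
        synth.SmearSpec(seed=1, n_fields=2, net_fraction=0.0))
    assert scan_slide(fields).net_fraction == 0.0


def test_anchor_conversion_is_a_product():
    fields, _ = synth.generate_smear(
        synth.SmearSpec(seed=1, n_fields=2, net_fraction=0.0))
    res = scan_slide(fields, anchor_per_ul=3000.0)
    assert res.net_count_per_ul == pytest.approx(
        res.net_fraction * 3000.0)


def test_scan_empty_field_list_rejected():
    with pytest.raises(DomainError):
        scan_slide([])


def test_tiff_round_trip(tmp_path, smear_fields):
    fields, _ = smear_fields
    p = tmp_path / "field.tiff"
    save_field_tiff(fields[0], p)
    again = load_field_tiff(p, pixel_size=fields[0].pixel_size)
    for ch in ("dapi", "cd11b", "despr"):
        assert np.allclose(again.channels[ch], fields[0].channels[ch],
                           atol=1e-3)


def test_nuclei_records_table(smear_fields):
    fields, _ = smear_fields
    res = scan_slide(fields[:2])
    df = nuclei_to_records(res.nuclei)
    assert len(df) == len(res.nuclei)
    assert {"circularity", "net_positive", "despr_cd11b_positive"} <= set(
        df.columns)
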
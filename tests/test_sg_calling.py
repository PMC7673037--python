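"""Dual-marker matching and stress-granule calling."""

import numpy as np
import pytest

from sgquant.puncta import PunctumRecord
from sgquant.sg_calling import (
    SGCallParams,
    call_stress_granules,
    match_puncta,
    per_cell_sg_counts,
)


def mk_punctum(pid, cell, pixels, channel="marker1", mean=200.0):
    fp = np.asarray(sorted(pixels), dtype=np.int64)
    return PunctumRecord(
        punctum_id=pid,
        channel=channel,
        cell_label=cell,
        centroid=(float(fp[:, 0].mean()), float(fp[:, 1].mean())),
        area=len(fp),
        mean_intensity=mean,
        integrated_intensity=mean * len(fp),
        peak_intensity=mean * 1.5,
        footprint=fp,
    )


def box(r0, c0, h, w):
    return [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)]


BG = (100.0, 5.0)


def test_identical_sets_pair_perfectly():
    p1 = [mk_punctum(1, 1, box(2, 2, 3, 3)), mk_punctum(2, 1, box(10, 10, 3, 3))]
    p2 = [mk_punctum(1, 1, box(2, 2, 3, 3), "marker2"), mk_punctum(2, 1, box(10, 10, 3, 3), "marker2")]
    res = match_puncta(p1, p2, SGCallParams())
    assert len(res.pairs) == 2
    assert res.unmatched_m1 == [] and res.unmatched_m2 == []
    assert all(a.punctum_id == b.punctum_id for a, b in res.pairs)


def test_disjoint_footprints_stay_unmatched():
    p1 = [mk_punctum(1, 1, box(2, 2, 3, 3))]
    p2 = [mk_punctum(1, 1, box(20, 20, 3, 3), "marker2")]
    res = match_puncta(p1, p2, SGCallParams())
    assert res.pairs == []
    assert len(res.unmatched_m1) == 1 and len(res.unmatched_m2) == 1


def test_multiway_overlap_resolved_by_largest_intersection():
    """One marker1 punctum overlapping marker2 puncta of 12 and 5 px^2 pairs
    with the larger intersection (brute-force optimum on this instance)."""
    a = mk_punctum(1, 1, box(0, 0, 4, 5))  # 20 px
    b_large = mk_punctum(1, 1, box(0, 0, 3, 4), "marker2")  # 12 px, all inside a
    b_small = mk_punctum(2, 1, box(3, 0, 2, 5), "marker2")  # overlaps 5 px of row 3
    res = match_puncta([a], [b_large, b_small], SGCallParams())
    assert len(res.pairs) == 1
    assert res.pairs[0][1].punctum_id == 1
    assert [p.punctum_id for p in res.unmatched_m2] == [2]


def test_matching_requires_same_cell():
    p1 = [mk_punctum(1, 1, box(2, 2, 3, 3))]
    p2 = [mk_punctum(1, 2, box(2, 2, 3, 3), "marker2")]  # same pixels, other cell
    assert match_puncta(p1, p2, SGCallParams()).pairs == []


def test_centroid_distance_rule():
    p1 = [mk_punctum(1, 1, box(2, 2, 3, 3))]
    p2 = [mk_punctum(1, 1, box(6, 6, 3, 3), "marker2")]  # no overlap, ~5.7 px apart
    params = SGCallParams(match_rule="centroid-distance", max_centroid_distance=8.0)
    assert len(match_puncta(p1, p2, params).pairs) == 1
    params = SGCallParams(match_rule="centroid-distance", max_centroid_distance=3.0)
    assert match_puncta(p1, p2, params).pairs == []


def _images_with_profile(fp, invert=False):
    img1 = np.full((32, 32), 100.0)
    img2 = np.full((32, 32), 100.0)
    for i, (r, c) in enumerate(fp):
        img1[r, c] = 150.0 + 10.0 * i
        img2[r, c] = (150.0 + 10.0 * (len(fp) - 1 - i)) if invert else img1[r, c]
    return img1, img2


def test_identical_profiles_called_and_inverted_rejected():
    fp = box(5, 5, 3, 3)
    a = mk_punctum(1, 1, fp)
    b = mk_punctum(1, 1, fp, "marker2")
    img1, img2 = _images_with_profile(fp)
    sgs = call_stress_granules([(a, b)], img1, img2, BG, BG, SGCallParams())
    assert len(sgs) == 1 and sgs[0].correlation == pytest.approx(1.0)
    img1, img2 = _images_with_profile(fp, invert=True)
    assert call_stress_granules([(a, b)], img1, img2, BG, BG, SGCallParams()) == []


def test_dim_puncta_fail_intensity_sufficiency():
    fp = box(5, 5, 3, 3)
    a = mk_punctum(1, 1, fp, mean=105.0)  # below bg mean + 2 SD = 110
    b = mk_punctum(1, 1, fp, "marker2", mean=200.0)
    img1, img2 = _images_with_profile(fp)
    assert call_stress_granules([(a, b)], img1, img2, BG, BG, SGCallParams()) == []


def test_tiny_union_footprint_rejected(caplog):
    fp = box(5, 5, 1, 3)  # 3 px
    a = mk_punctum(1, 1, fp)
    b = mk_punctum(1, 1, fp, "marker2")
    img1, img2 = _images_with_profile(fp)
    assert call_stress_granules([(a, b)], img1, img2, BG, BG, SGCallParams()) == []


def test_correlation_threshold_monotonicity():
    """Raising the correlation threshold never increases the SG count."""
    rng = np.random.default_rng(5)
    pairs, img1, img2 = [], np.full((64, 64), 100.0), np.full((64, 64), 100.0)
    for i in range(8):
        fp = box(2 + 7 * i, 2, 3, 3)
        a = mk_punctum(i + 1, 1, fp)
        b = mk_punctum(i + 1, 1, fp, "marker2")
        prof = rng.normal(60, 20, 9)
        noise = rng.normal(0, 25, 9)
        for j, (r, c) in enumerate(fp):
            img1[r, c] = 100 + prof[j]
            img2[r, c] = 100 + prof[j] + noise[j]
        pairs.append((a, b))
    counts = [
        len(call_stress_granules(pairs, img1, img2, BG, BG,
                                 SGCallParams(correlation_threshold=t)))
        for t in (0.0, 0.3, 0.5, 0.8, 0.95)
    ]
    assert counts == sorted(counts, reverse=True)
    assert counts[0] > counts[-1]  # the sweep actually bites


def test_marker_swap_symmetry(fields, small_spec, config):
    """Swapping the two marker channels yields the same SG set."""
    from sgquant.pipeline import quantify_field
    from sgquant.io import Field

    channels, _ = fields.field(small_spec)
    swapped = dict(channels)
    swapped["marker1"], swapped["marker2"] = channels["marker2"], channels["marker1"]
    res = quantify_field(Field(channels=channels, field_id="a"), config)
    res_sw = quantify_field(Field(channels=swapped, field_id="b"), config)
    key = lambda sgs: sorted((sg.cell_label, round(sg.centroid[0], 6), round(sg.centroid[1], 6),
                              round(sg.correlation, 9)) for sg in sgs)
    assert key(res.stress_granules) == key(res_sw.stress_granules)


def test_no_punctum_participates_in_two_sgs(fields, small_spec, config):
    from sgquant.pipeline import quantify_field
    from sgquant.io import Field

    channels, _ = fields.field(small_spec)
    res = quantify_field(Field(channels=channels, field_id="a"), config)
    m1_ids = [sg.punctum_id_m1 for sg in res.stress_granules]
    m2_ids = [sg.punctum_id_m2 for sg in res.stress_granules]
    assert len(m1_ids) == len(set(m1_ids)) and len(m2_ids) == len(set(m2_ids))


def test_per_cell_counts_and_conservation():
    cells = np.zeros((20, 20), np.int32)
    cells[0:10, :] = 1
    cells[10:20, :] = 2
    sgs = [
        type("SG", (), {"cell_label": 1})(),
        type("SG", (), {"cell_label": 1})(),
        type("SG", (), {"cell_label": 1})(),
        type("SG", (), {"cell_label": 9})(),  # dropped cell -> discarded
    ]
    table = per_cell_sg_counts(sgs, cells)
    assert table.set_index("cell_label")["sg_count"].to_dict() == {1: 3, 2: 0}
    assert table.set_index("cell_label")["sg_positive"].to_dict() == {1: True, 2: False}
    assert table["sg_count"].sum() == 3


def test_params_validation():
    with pytest.raises(ValueError):
        SGCallParams(correlation_threshold=1.5)
    with pytest.raises(ValueError):
        SGCallParams(match_rule="nearest")
    with pytest.raises(ValueError):
        SGCallParams(correlation_domain="blend")
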
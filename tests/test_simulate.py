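"""Generator correctness: determinism, planted-truth invariants, count model,
chance-coincidence geometry and screen-plate structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from sgquant.simulate import (
    PRESENCE_BOTH,
    PRESENCE_M1,
    PRESENCE_M2,
    FieldSpec,
    PlateSpec,
    generate_field,
    generate_screen_plate,
)

SMALL = dict(width=256, height=256, n_cells=14)


def test_fixed_seed_is_bit_identical():
    spec = FieldSpec(seed=3, **SMALL)
    ch1, gt1 = generate_field(spec)
    ch2, gt2 = generate_field(spec)
    for role in ch1:
        np.testing.assert_array_equal(ch1[role], ch2[role])
    pd.testing.assert_frame_equal(gt1.puncta, gt2.puncta)
    np.testing.assert_array_equal(gt1.cell_labels, gt2.cell_labels)


def test_different_seeds_differ():
    ch1, _ = generate_field(FieldSpec(seed=3, **SMALL))
    ch2, _ = generate_field(FieldSpec(seed=4, **SMALL))
    assert not np.array_equal(ch1["marker1"], ch2["marker1"])


@pytest.mark.parametrize("rho,presences", [(1.0, {PRESENCE_BOTH}), (0.0, {PRESENCE_M1, PRESENCE_M2})])
def test_coincidence_fraction_extremes(rho, presences):
    _, gt = generate_field(FieldSpec(seed=5, coincidence_fraction=rho, **SMALL))
    assert len(gt.puncta) > 0
    assert set(gt.puncta["presence"]) == presences


def test_spec_validation():
    with pytest.raises(ValueError):
        FieldSpec(coincidence_fraction=1.5)
    with pytest.raises(ValueError):
        FieldSpec(snr=0)
    with pytest.raises(ValueError):
        FieldSpec(nucleus_radius_range=(10.0, 20.0), cell_radius_range=(12.0, 15.0))


def test_impossible_packing_raises():
    with pytest.raises(ValueError, match="cannot place"):
        generate_field(FieldSpec(width=128, height=128, n_cells=200))


def test_puncta_lie_in_their_cells_cytoplasm():
    _, gt = generate_field(FieldSpec(seed=11, **SMALL))
    cyto = (gt.cell_labels > 0) & (gt.nuclei_labels == 0)
    for p in gt.puncta.itertuples():
        r, c = int(round(p.row)), int(round(p.col))
        assert cyto[r, c]
        assert gt.cell_labels[r, c] == p.cell_label


def test_true_sg_count_equals_both_sites():
    _, gt = generate_field(FieldSpec(seed=11, coincidence_fraction=0.5, **SMALL))
    both = gt.puncta[gt.puncta["presence"] == PRESENCE_BOTH].groupby("cell_label").size()
    for row in gt.cells.itertuples():
        assert row.true_sg_count == int(both.get(row.label, 0))


def test_nuclei_disjoint_and_inside_cells():
    _, gt = generate_field(FieldSpec(seed=2, **SMALL))
    assert (gt.cell_labels[gt.nuclei_labels > 0] == gt.nuclei_labels[gt.nuclei_labels > 0]).all()


def test_per_cell_counts_follow_negative_binomial_moments():
    """Variance of per-channel per-cell counts ~ mu + mu^2/k."""
    mu, k = 5.0, 2.0
    counts = []
    for seed in range(8):
        _, gt = generate_field(
            FieldSpec(seed=seed, puncta_per_cell_mean=mu, puncta_dispersion=k,
                      coincidence_fraction=0.5, **SMALL)
        )
        m1 = gt.puncta[gt.puncta["amplitude_m1"] > 0].groupby("cell_label").size()
        counts.extend(int(m1.get(lab, 0)) for lab in gt.cells["label"])
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    assert n > 80
    # mean within 4 SE; variance within 35% of mu + mu^2/k
    se_mean = np.sqrt((mu + mu**2 / k) / n)
    assert abs(counts.mean() - mu) < 4 * se_mean
    target_var = mu + mu**2 / k
    assert 0.65 * target_var < counts.var(ddof=1) < 1.35 * target_var


@pytest.mark.parametrize("snr,r_min", [(12.0, 0.75), (30.0, 0.9)])
def test_coincident_puncta_profiles_correlate(snr, r_min):
    """Rendered marker channels correlate strongly over a both-site's
    footprint and not over single-channel sites.  Peak shot noise scales with
    the signal, so pixelwise r saturates around 0.85 at snr ~10-12 and
    approaches 1 as snr grows."""
    spec = FieldSpec(seed=13, coincidence_fraction=0.5, snr=snr,
                     min_punctum_separation=10.0, **SMALL)
    ch, gt = generate_field(spec)
    # footprint = pixels within 2 sigma of the center, where the rendered
    # profile dominates the noise
    half = 3
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    inside = (yy**2 + xx**2) <= (2 * spec.punctum_sigma) ** 2
    rs_both, rs_single = [], []
    for p in gt.puncta.itertuples():
        r0, c0 = int(round(p.row)), int(round(p.col))
        if not (half <= r0 < spec.height - half and half <= c0 < spec.width - half):
            continue
        w1 = ch["marker1"][r0 - half:r0 + half + 1, c0 - half:c0 + half + 1][inside]
        w2 = ch["marker2"][r0 - half:r0 + half + 1, c0 - half:c0 + half + 1][inside]
        r = np.corrcoef(w1, w2)[0, 1]
        (rs_both if p.presence == PRESENCE_BOTH else rs_single).append(r)
    assert np.mean(rs_both) > r_min
    assert np.mean(rs_single) < 0.5


def test_chance_coincidence_matches_geometric_expectation():
    """At rho=0 the number of cross-channel center pairs closer than d matches
    the exact per-geometry expectation N1*N2 * sum_x |disk(x,d) ∩ A| / |A|^2
    (computed by convolving the cytoplasm mask with a disk kernel)."""
    d = 3.0
    n_per = 20
    expected_total = 0.0
    observed_total = 0
    for seed in range(50):
        spec = FieldSpec(width=160, height=160, n_cells=4, seed=seed,
                         coincidence_fraction=0.0, fixed_puncta_per_cell=n_per)
        _, gt = generate_field(spec)
        yy, xx = np.mgrid[-4:5, -4:5]
        kernel = ((yy**2 + xx**2) <= d**2).astype(float)
        cyto = (gt.cell_labels > 0) & (gt.nuclei_labels == 0)
        for lab in gt.cells["label"]:
            mask = ((gt.cell_labels == lab) & (gt.nuclei_labels == 0)).astype(float)
            area = mask.sum()
            if area == 0:
                continue
            inter = ndimage.convolve(mask, kernel, mode="constant")
            expected_total += n_per * n_per * float((mask * inter).sum()) / area**2
            pts = gt.puncta[gt.puncta["cell_label"] == lab]
            p1 = pts[pts["amplitude_m1"] > 0]
            p2 = pts[pts["amplitude_m2"] > 0]
            dr = p1["row"].to_numpy()[:, None] - p2["row"].to_numpy()[None, :]
            dc = p1["col"].to_numpy()[:, None] - p2["col"].to_numpy()[None, :]
            observed_total += int((np.hypot(dr, dc) <= d).sum())
    # Poisson-scale error on the pair count
    assert abs(observed_total - expected_total) < 4 * np.sqrt(expected_total) + 0.1 * expected_total


# ---------------------------------------------------------------- screen plates


def test_plate_has_requested_wells():
    plate = generate_screen_plate(PlateSpec(n_drugs=1120, n_control_wells=96, seed=1))
    assert (plate["kind"] == "drug").sum() == 1120
    assert (plate["kind"] == "control").sum() == 96


def test_plate_determinism_and_substreams():
    spec = PlateSpec(n_drugs=50, n_control_wells=8, seed=4)
    p1 = generate_screen_plate(spec)
    p2 = generate_screen_plate(spec)
    pd.testing.assert_frame_equal(p1, p2)
    # adding wells must not perturb earlier wells (counter-based substreams)
    bigger = generate_screen_plate(PlateSpec(n_drugs=60, n_control_wells=8, seed=4))
    pd.testing.assert_frame_equal(p1, bigger.iloc[: len(p1)].reset_index(drop=True))


def test_zero_effect_hits_indistinguishable_from_nulls():
    """With hit_effect=0, planted-'hit' wells follow the null distribution."""
    hit_vals, null_vals = [], []
    hits = frozenset(range(1, 21))
    for seed in range(100):
        plate = generate_screen_plate(
            PlateSpec(n_drugs=60, n_control_wells=4, hit_indices=hits, hit_effect=0.0, seed=seed)
        )
        drugs = plate[plate["kind"] == "drug"]
        hit_vals.extend(drugs.loc[drugs["is_true_hit"], "mean_granules_per_cell"])
        null_vals.extend(drugs.loc[~drugs["is_true_hit"], "mean_granules_per_cell"])
    _, p = stats.ks_2samp(hit_vals, null_vals)
    assert p > 0.01


def test_hit_effect_four_gives_mean_z_near_four():
    spec = PlateSpec(n_drugs=200, n_control_wells=2000, hit_indices=frozenset(range(1, 51)),
                     hit_effect=4.0, seed=9)
    plate = generate_screen_plate(spec)
    controls = plate.loc[plate["kind"] == "control", "mean_granules_per_cell"]
    drugs = plate[plate["kind"] == "drug"]
    z = (drugs["mean_granules_per_cell"] - controls.mean()) / controls.std(ddof=1)
    mean_hit_z = z[drugs["is_true_hit"].to_numpy()].mean()
    assert abs(mean_hit_z - 4.0) < 3 / np.sqrt(50)  # z SD 1, n=50 hits


def test_normoxia_arm_shifts_only_inducers():
    spec = PlateSpec(n_drugs=100, n_control_wells=2000, hit_indices=frozenset({1, 2}),
                     normoxia_inducer_indices=frozenset({3, 4}), hit_effect=6.0, seed=2)
    norm = generate_screen_plate(spec, arm="normoxia")
    controls = norm.loc[norm["kind"] == "control", "mean_granules_per_cell"]
    z = (norm["mean_granules_per_cell"] - controls.mean()) / controls.std(ddof=1)
    assert (z[norm["is_normoxia_inducer"].to_numpy()] > 3).all()
    assert (z[norm["is_true_hit"].to_numpy() & ~norm["is_normoxia_inducer"].to_numpy()] < 3).all()


def test_plate_spec_validation():
    with pytest.raises(ValueError):
        PlateSpec(hit_effect=-1.0)
    with pytest.raises(ValueError):
        PlateSpec(n_drugs=10, hit_indices=frozenset({11}))
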
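"""Joint histograms, posterior estimation, averaging and constraints."""

import numpy as np
import pytest

from utebone import (
    AIR,
    BONE,
    SOFT,
    DualEchoVolume,
    HistogramBinning,
    JointHistogramSet,
    PosteriorMap,
    ScalarVolume,
    VoxelGrid,
    accumulate_histograms,
    apply_prior_constraints,
    average_posteriors,
    compute_posterior,
    load_posterior_map,
    mean_ct_map,
    save_posterior_map,
)
from utebone.errors import ConfigurationError, ContractError, GeometryError


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.floats(min_value=-1e5, max_value=1e5, allow_nan=False))
def test_binning_index_contract(value):
    """Half-open bins, final bin closed, out-of-range clamps to edges."""
    binning = HistogramBinning()
    idx = int(binning.index(np.array([value]))[0])
    assert 0 <= idx < binning.nbins
    if binning.low <= value < binning.high:
        low_edge = binning.low + idx * binning.width
        assert low_edge <= value < low_edge + binning.width
    elif value < binning.low:
        assert idx == 0
    else:
        assert idx == binning.nbins - 1


def make_inputs(e1, e2, labels, ct):
    grid = VoxelGrid.centered(np.asarray(e1).shape, (1.0, 1.0, 1.0))
    vol = DualEchoVolume(
        ScalarVolume(grid, np.asarray(e1, float), "MR_echo1"),
        ScalarVolume(grid, np.asarray(e2, float), "MR_echo2"),
        te1=0.03,
        te2=1.7,
    )
    return (
        vol,
        ScalarVolume(grid, np.asarray(labels, np.int16), "label"),
        ScalarVolume(grid, np.asarray(ct, float), "CT"),
    )


def empty_hist(binning=None) -> JointHistogramSet:
    binning = binning or HistogramBinning()
    n = binning.nbins
    return JointHistogramSet(binning, np.zeros((3, n, n), np.int64), np.zeros((n, n)))


def test_single_bone_voxel_counts_once():
    vol, labels, ct = make_inputs([[[2000.0]]], [[[800.0]]], [[[BONE]]], [[[1200.0]]])
    h = accumulate_histograms(vol, labels, ct)
    assert h.counts[BONE].sum() == 1
    assert h.counts[AIR].sum() == 0 and h.counts[SOFT].sum() == 0
    assert h.ct_sum.sum() == 1200.0


def test_total_count_conserved_on_phantom(default_cohort):
    case = default_cohort[0]
    h = accumulate_histograms(case.ute, case.labels, case.ct)
    assert int(h.counts.sum()) == case.labels.values.size


def test_counts_match_brute_force_recount(rng):
    binning = HistogramBinning(0.0, 1000.0, 10)
    e1 = rng.uniform(-50, 1100, size=(6, 6, 6))  # includes out-of-range clamping
    e2 = rng.uniform(-50, 1100, size=(6, 6, 6))
    e1, e2 = np.abs(e1), np.abs(e2)
    labels = rng.integers(0, 3, size=(6, 6, 6))
    ct = rng.uniform(-1000, 2000, size=(6, 6, 6))
    vol, lab_vol, ct_vol = make_inputs(e1, e2, labels, ct)
    h = accumulate_histograms(vol, lab_vol, ct_vol, binning)

    expected = np.zeros((3, 10, 10), dtype=int)
    ct_sum = np.zeros((10, 10))
    for v1, v2, lb, hu in zip(e1.ravel(), e2.ravel(), labels.ravel(), ct.ravel()):
        i = min(int(v1 // 100), 9)
        j = min(int(v2 // 100), 9)
        expected[lb, i, j] += 1
        ct_sum[i, j] += hu
    np.testing.assert_array_equal(h.counts, expected)
    np.testing.assert_allclose(h.ct_sum, ct_sum)


def test_grid_mismatch_rejected():
    vol, labels, ct = make_inputs(np.zeros((3, 3, 3)), np.zeros((3, 3, 3)),
                                  np.zeros((3, 3, 3)), np.zeros((3, 3, 3)))
    other = ScalarVolume(VoxelGrid.centered((4, 4, 4), (1.0, 1.0, 1.0)),
                         np.zeros((4, 4, 4)), "CT")
    with pytest.raises(GeometryError):
        accumulate_histograms(vol, labels, other)


def test_mean_ct_map_values_and_empty_bins():
    h = empty_hist()
    h.counts[BONE, 5, 5] = 1
    h.ct_sum[5, 5] = 700.0
    m = mean_ct_map(h)
    assert m[5, 5] == 700.0
    assert np.isnan(m[0, 0])  # empty bin is undefined, never 0 HU (water)


def test_mean_ct_map_matches_direct_average(default_cohort):
    case = default_cohort[1]
    h = accumulate_histograms(case.ute, case.labels, case.ct)
    m = mean_ct_map(h)
    i = h.binning.index(case.ute.echo1.values.ravel())
    j = h.binning.index(case.ute.echo2.values.ravel())
    # spot-check a handful of populated bins against per-voxel averaging
    populated = np.argwhere(h.total >= 5)[::200]
    for bi, bj in populated:
        sel = (i == bi) & (j == bj)
        assert m[bi, bj] == pytest.approx(case.ct.values.ravel()[sel].mean())


def test_posterior_normalization_with_count_clipping():
    h = empty_hist()
    h.counts[SOFT, 2, 2], h.counts[BONE, 2, 2] = 8, 2  # total 10 -> reliable
    h.counts[SOFT, 3, 3], h.counts[BONE, 3, 3] = 3, 1  # total 4 -> clipped
    pmap = compute_posterior(h, min_count=10)
    np.testing.assert_allclose(pmap.probs[:, 2, 2], [0.0, 0.8, 0.2])
    assert pmap.reliable[2, 2]
    np.testing.assert_allclose(pmap.probs[:, 3, 3], [0.0, 0.3, 0.1])
    assert not pmap.reliable[3, 3]
    assert pmap.probs[:, 3, 3].sum() == pytest.approx(0.4)
    np.testing.assert_array_equal(pmap.probs[:, 0, 0], 0.0)
    assert not pmap.reliable[0, 0]


def test_reliable_bins_sum_to_one(default_cohort):
    case = default_cohort[2]
    h = accumulate_histograms(case.ute, case.labels, case.ct)
    pmap = compute_posterior(h)
    sums = pmap.probs.sum(axis=0)
    np.testing.assert_allclose(sums[pmap.reliable], 1.0, atol=1e-9)
    assert (sums[~pmap.reliable] <= 1.0 + 1e-9).all()


def test_averaging_identity_and_mean():
    h = empty_hist()
    h.counts[SOFT, 1, 1], h.counts[BONE, 1, 1] = 2, 8
    a = compute_posterior(h)
    assert average_posteriors([a]).probs[BONE, 1, 1] == a.probs[BONE, 1, 1]
    same = average_posteriors([a, a, a])
    np.testing.assert_allclose(same.probs, a.probs)
    h2 = empty_hist()
    h2.counts[SOFT, 1, 1], h2.counts[BONE, 1, 1] = 4, 6
    b = compute_posterior(h2)
    avg = average_posteriors([a, b])
    assert avg.probs[BONE, 1, 1] == pytest.approx((0.8 + 0.6) / 2)


def test_averaging_requires_matching_binning():
    a = compute_posterior(empty_hist())
    b = compute_posterior(empty_hist(HistogramBinning(0.0, 6000.0, 120)))
    with pytest.raises(ConfigurationError):
        average_posteriors([a, b])


def test_average_reliability_majority_vote():
    h_hi = empty_hist()
    h_hi.counts[SOFT, 4, 4] = 50
    h_lo = empty_hist()
    h_lo.counts[SOFT, 4, 4] = 2
    reliable = compute_posterior(h_hi)
    sparse = compute_posterior(h_lo)
    assert average_posteriors([reliable, sparse]).reliable[4, 4]  # 1 of 2 = half
    assert not average_posteriors([reliable, sparse, sparse]).reliable[4, 4]


def constrained_fixture_map():
    binning = HistogramBinning()
    n = binning.nbins
    probs = np.zeros((3, n, n))
    probs[AIR] = 0.2
    probs[SOFT] = 0.5
    probs[BONE] = 0.3
    return PosteriorMap(binning, probs, np.ones((n, n), bool))


def bin_of(binning, e1, e2):
    return int(binning.index(np.array([e1]))[0]), int(binning.index(np.array([e2]))[0])


def test_constraints_zero_the_published_regions():
    pmap = apply_prior_constraints(constrained_fixture_map())
    binning = pmap.binning
    i, j = bin_of(binning, 3000.0, 3000.0)  # e1+e2 > 4000 -> never air
    assert pmap.probs[AIR, i, j] == 0.0
    i, j = bin_of(binning, 1000.0, 2000.0)  # e2 > e1 -> never bone
    assert pmap.probs[BONE, i, j] == 0.0
    i, j = bin_of(binning, 9000.0, 1000.0)  # e1 > 8000 -> never bone
    assert pmap.probs[BONE, i, j] == 0.0
    i, j = bin_of(binning, 7000.0, 1000.0)  # e1-e2 > 4000 -> never bone
    assert pmap.probs[BONE, i, j] == 0.0
    i, j = bin_of(binning, 1500.0, 700.0)  # unconstrained bin untouched
    np.testing.assert_allclose(pmap.probs[:, i, j], [0.2, 0.5, 0.3])


def test_constraints_conserve_mass_and_flag():
    before = constrained_fixture_map()
    after = apply_prior_constraints(before)
    np.testing.assert_allclose(after.probs.sum(axis=0), before.probs.sum(axis=0), atol=1e-12)
    assert after.constrained and not before.constrained
    assert after.probs.min() >= 0.0 and after.probs.max() <= 1.0
    with pytest.raises(ContractError):
        apply_prior_constraints(after)


def test_posterior_map_round_trip(tmp_path, default_cohort):
    case = default_cohort[3]
    h = accumulate_histograms(case.ute, case.labels, case.ct)
    pmap = apply_prior_constraints(compute_posterior(h))
    path = tmp_path / "map.npz"
    save_posterior_map(pmap, path)
    back = load_posterior_map(path)
    np.testing.assert_array_equal(back.probs, pmap.probs)
    np.testing.assert_array_equal(back.reliable, pmap.reliable)
    assert back.binning == pmap.binning
    assert back.constrained and back.min_count == pmap.min_count
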
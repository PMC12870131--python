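"""Voxelwise GLM, smoothness estimation, Monte-Carlo cluster thresholding."""

import numpy as np
import pytest
from scipy import ndimage

from fixtract.clusters import (StatMap, assign_atlas_labels,
                               estimate_smoothness, label_clusters,
                               montecarlo_cluster_threshold,
                               permutation_cluster_threshold, voxelwise_glm)
from fixtract.fixel import MetricVolume

AFF = np.diag([2.0, 2.0, 2.0, 1.0])


def _maps(data):
    return [MetricVolume(d, AFF) for d in data]


def test_glm_identical_groups_zero_t():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(8, 8, 8))
    data = [base.copy() for _ in range(12)]
    groups = np.array(["AUD"] * 6 + ["control"] * 6)
    ages = np.linspace(30, 60, 12)
    stat, _ = voxelwise_glm(_maps(data), groups, ages)
    np.testing.assert_allclose(stat.t[stat.defined], 0.0, atol=1e-8)
    assert stat.df == 12 - 3


def test_glm_zero_noise_offset_reports_capped_t():
    base = np.zeros((4, 4, 4))
    data = [base.copy() for _ in range(6)] + [base + 1.0 for _ in range(6)]
    groups = np.array(["control"] * 6 + ["AUD"] * 6)
    ages = np.r_[np.linspace(30, 60, 6), np.linspace(30, 60, 6)]
    stat, _ = voxelwise_glm(_maps(data), groups, ages)
    assert np.all(np.abs(stat.t[stat.defined]) >= 1e5)
    assert np.all(np.isfinite(stat.t[stat.defined]))


def test_glm_undefined_voxels_excluded_and_design_errors():
    rng = np.random.default_rng(1)
    data = [rng.normal(size=(5, 5, 5)) for _ in range(8)]
    data[0][2, 2, 2] = np.nan
    groups = np.array(["AUD"] * 4 + ["control"] * 4)
    ages = np.linspace(30, 60, 8)
    stat, resid = voxelwise_glm(_maps(data), groups, ages)
    assert not stat.defined[2, 2, 2]
    assert np.isnan(stat.t[2, 2, 2]) and np.all(np.isnan(resid[:, 2, 2, 2]))

    with pytest.raises(ValueError):
        voxelwise_glm(_maps(data[:4]), groups[:4], np.full(4, 50.0))  # <3/group


def test_glm_null_pvalue_calibration():
    """Pure-noise cohorts: the fraction of p < 0.05 voxels is ~0.05."""
    rng = np.random.default_rng(2)
    n = 40
    data = [rng.normal(size=(12, 12, 12)) for _ in range(n)]
    groups = np.array(["AUD"] * 20 + ["control"] * 20)
    ages = rng.uniform(30, 65, n)
    stat, _ = voxelwise_glm(_maps(data), groups, ages)
    frac = (stat.pvalues()[stat.defined] < 0.05).mean()
    v = 12**3
    ci = 1.96 * np.sqrt(0.05 * 0.95 / v)
    assert abs(frac - 0.05) < 3 * ci + 0.005


def test_smoothness_white_noise_floored_at_voxel():
    rng = np.random.default_rng(3)
    resid = rng.normal(size=(6, 16, 16, 16))
    est = estimate_smoothness(resid, voxel_size=2.0)
    assert est["fwhm"] == pytest.approx(2.0, rel=0.05)


def test_smoothness_recovers_known_kernel():
    """Noise smoothed with a FWHM=6 mm kernel is estimated within 15%."""
    rng = np.random.default_rng(4)
    sigma_vox = 6.0 / (2 * np.sqrt(2 * np.log(2))) / 2.0
    resid = np.stack([ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)),
                                              sigma_vox) for _ in range(6)])
    est = estimate_smoothness(resid, voxel_size=2.0)
    assert abs(est["fwhm"] - 6.0) / 6.0 < 0.15


def test_smoothness_constant_residuals_error():
    with pytest.raises(ValueError):
        estimate_smoothness(np.zeros((3, 8, 8, 8)), voxel_size=2.0)


def test_mc_threshold_independent_voxels_small():
    """At fwhm = voxel size and alpha 1e-4 on a 30^3 grid, ~2.7 suprathreshold
    voxels are expected per map and adjacency is improbable: threshold 1-2."""
    thr = montecarlo_cluster_threshold((30, 30, 30), fwhm=2.0, voxel_size=2.0,
                                       voxel_alpha=1e-4, fw_alpha=0.05,
                                       n_iter=400, seed=0)
    assert thr.min_cluster_size in (1, 2)


def test_mc_threshold_limits_and_monotonicity():
    thr1 = montecarlo_cluster_threshold((20, 20, 20), fwhm=2.0, voxel_size=2.0,
                                        fw_alpha=0.999, n_iter=200, seed=1)
    assert thr1.min_cluster_size == 1

    lo = montecarlo_cluster_threshold((20, 20, 20), fwhm=2.0, voxel_size=2.0,
                                      n_iter=300, seed=2)
    hi = montecarlo_cluster_threshold((20, 20, 20), fwhm=8.0, voxel_size=2.0,
                                      n_iter=300, seed=2)
    assert hi.min_cluster_size >= lo.min_cluster_size

    with pytest.raises(ValueError):
        montecarlo_cluster_threshold((20,) * 3, fwhm=1.0, voxel_size=2.0,
                                     n_iter=300, seed=0)
    with pytest.raises(ValueError):
        montecarlo_cluster_threshold((20,) * 3, fwhm=2.0, voxel_size=2.0,
                                     n_iter=100, seed=0)


def test_permutation_threshold_null_distribution():
    """On white-noise cohorts the permutation threshold stays small (isolated
    suprathreshold voxels), and a planted effect is not needed for it to be
    well defined."""
    rng = np.random.default_rng(9)
    maps = _maps([rng.normal(size=(14, 14, 14)) for _ in range(20)])
    groups = np.array(["AUD"] * 10 + ["control"] * 10)
    ages = rng.uniform(30, 60, 20)
    thr = permutation_cluster_threshold(maps, groups, ages, voxel_alpha=1e-3,
                                        n_perm=200, seed=0)
    assert 1 <= thr.min_cluster_size <= 4
    assert len(thr.max_size_distribution) == 200
    with pytest.raises(ValueError):
        permutation_cluster_threshold(maps, groups, ages, n_perm=50, seed=0)


def _statmap(t):
    t = np.asarray(t, dtype=float)
    return StatMap(t=t, df=30, defined=np.ones(t.shape, dtype=bool), affine=AFF)


def test_label_clusters_empty_and_size_filter():
    stat = _statmap(np.zeros((8, 8, 8)))
    assert len(label_clusters(stat)) == 0

    t = np.zeros((10, 10, 4))
    t[1:4, 1, 1] = 10.0          # 3-voxel blob
    t[6:9, 6, 1] = 10.0
    t[6:9, 7, 1] = 10.0          # with neighbours: >= 5 voxels... keep distinct
    t[6, 8, 1] = 10.0
    table = label_clusters(_statmap(t), min_size=4)
    assert len(table) == 1
    assert table.clusters[0].volume_mm3 == pytest.approx(
        table.clusters[0].n_voxels * 8.0)
    assert table.clusters[0].n_voxels >= 4


def test_label_clusters_connectivity_modes():
    t = np.zeros((6, 6, 6))
    t[1, 1, 1] = 8.0
    t[2, 2, 2] = 8.0             # corner contact only
    assert len(label_clusters(_statmap(t), connectivity=26)) == 1
    assert len(label_clusters(_statmap(t), connectivity=6)) == 2


def test_label_clusters_sign_separated():
    t = np.zeros((8, 8, 4))
    t[1:3, 1, 1] = 9.0
    t[3:5, 1, 1] = -9.0          # adjacent but opposite sign
    table = label_clusters(_statmap(t))
    assert len(table) == 2
    signs = sorted(np.sign(c.peak_t) for c in table.clusters)
    assert signs == [-1, 1]


def test_label_clusters_centre_and_peak():
    t = np.zeros((10, 6, 6))
    t[2:5, 2, 2] = [5.0, 7.0, 6.0]
    table = label_clusters(_statmap(t))
    c = table.clusters[0]
    assert c.peak_t == pytest.approx(7.0)
    np.testing.assert_allclose(c.centre_world, [6.0, 4.0, 4.0])  # voxel 3,2,2


def test_atlas_labeling_modal_tie_and_background():
    t = np.zeros((10, 4, 4))
    t[0:5, 1, 1] = 9.0
    table = label_clusters(_statmap(t))
    atlas = np.zeros((10, 4, 4), dtype=int)
    atlas[0:3, 1, 1] = 1              # 3 voxels label 1
    atlas[3:5, 1, 1] = 2              # 2 voxels label 2
    names = {1: "cingulum", 2: "fornix"}
    out = assign_atlas_labels(table, atlas, names)
    assert out.clusters[0].label == "cingulum"

    # cluster fully in background
    t2 = np.zeros((10, 4, 4))
    t2[6:9, 2, 2] = 9.0
    tb = assign_atlas_labels(label_clusters(_statmap(t2)),
                             np.zeros((10, 4, 4), dtype=int), names)
    assert tb.clusters[0].label == "unlabeled"

    # missing name -> error
    atlas3 = np.full((10, 4, 4), 7, dtype=int)
    with pytest.raises(KeyError):
        assign_atlas_labels(label_clusters(_statmap(t)), atlas3, names)


def test_planted_cluster_detected_with_correct_centre():
    """A contiguous planted decrease well above noise is found with its mass
    centre inside the planted region, and labeling is subject-order
    invariant."""
    rng = np.random.default_rng(7)
    shape = (16, 16, 16)
    region = np.zeros(shape, dtype=bool)
    region[5:10, 5:10, 5:10] = True
    n = 30
    data, groups, ages = [], [], []
    for i in range(n):
        m = rng.normal(0, 0.02, size=shape) + 1.0
        g = "AUD" if i < 15 else "control"
        if g == "AUD":
            m[region] -= 0.1            # 5x noise sd
        data.append(m)
        groups.append(g)
        ages.append(rng.uniform(30, 60))
    stat, _ = voxelwise_glm(_maps(data), np.array(groups), np.array(ages))
    table = label_clusters(stat, voxel_alpha=1e-4, min_size=5)
    assert len(table) >= 1
    c = max(table.clusters, key=lambda c: c.n_voxels)
    centre_vox = np.round(c.centre_world / 2.0).astype(int)
    assert region[tuple(centre_vox)]
    assert c.peak_t < 0

    # permuting subjects leaves the cluster table unchanged
    perm = rng.permutation(n)
    stat2, _ = voxelwise_glm(_maps([data[i] for i in perm]),
                             np.array(groups)[perm], np.array(ages)[perm])
    table2 = label_clusters(stat2, voxel_alpha=1e-4, min_size=5)
    assert len(table2) == len(table)
    np.testing.assert_allclose(
        sorted(c.volume_mm3 for c in table.clusters),
        sorted(c.volume_mm3 for c in table2.clusters))
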
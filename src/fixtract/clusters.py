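"""Voxelwise group comparison with Monte-Carlo cluster-size correction.

The whole-brain analysis compares the weighted metric maps of the two cohorts
voxel by voxel with an age-corrected general linear model (with one binary
factor plus a covariate, the group F statistic equals t^2, i.e. a
single-factor ANOVA corrected for age).  Voxels are thresholded at an
uncorrected two-sided p < 1e-4 and familywise error is controlled by
discarding suprathreshold clusters smaller than a Monte-Carlo-calibrated
minimum size, following the classical cluster-size thresholding approach:
simulate smooth Gaussian null maps at the residual smoothness, record the
maximal cluster size per map, and keep the smallest size whose exceedance
probability is below the familywise alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fixel import MetricVolume

T_CAP = 1e6  # sentinel for zero-residual-variance voxels


@dataclass
class StatMap:
    """Per-voxel t statistics for the group effect."""

    t: np.ndarray
    df: int
    defined: np.ndarray
    affine: np.ndarray

    def pvalues(self) -> np.ndarray:
        p = np.full(self.t.shape, np.nan)
        p[self.defined] = 2 * stats.t.sf(np.abs(self.t[self.defined]), self.df)
        return p


@dataclass
class Cluster:
    members: np.ndarray      # (M, 3) voxel indices
    volume_mm3: float
    centre_world: np.ndarray  # (3,) mm
    peak_t: float            # signed
    label: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.members)


@dataclass
class ClusterTable:
    clusters: list[Cluster] = field(default_factory=list)
    metric: str = ""

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(metric=self.metric, x=c.centre_world[0], y=c.centre_world[1],
                     z=c.centre_world[2], volume_mm3=c.volume_mm3, t=c.peak_t,
                     label=c.label) for c in self.clusters]
        return pd.DataFrame(rows, columns=["metric", "x", "y", "z",
                                           "volume_mm3", "t", "label"])

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ClusterThreshold:
    """Monte-Carlo-calibrated minimum cluster size."""

    metric: str
    min_cluster_size: int
    voxel_alpha: float
    fw_alpha: float
    n_montecarlo: int
    fwhm_mm: float
    seed: int
    max_size_distribution: np.ndarray | None = None


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def voxelwise_glm(maps: list[MetricVolume], groups: np.ndarray,
                  ages: np.ndarray) -> tuple[StatMap, np.ndarray]:
    """OLS of wM on {intercept, group, age} per voxel; t for the group term.

    ``groups`` is any two-level labelling (the indicator is 1 for the first
    group encountered in sorted order's complement — explicitly: 1 for "AUD"
    when present, else for the lexicographically last level).  Returns the
    stat map and the (n_subjects, X, Y, Z) residual array for smoothness
    estimation.
    """
    groups = np.asarray(groups)
    ages = np.asarray(ages, dtype=float)
    levels = sorted(set(groups.tolist()))
    if len(levels) != 2:
        raise ValueError("exactly two group levels required")
    target = "AUD" if "AUD" in levels else levels[-1]
    g = (groups == target).astype(float)
    if g.sum() < 3 or (1 - g).sum() < 3:
        raise ValueError("need at least 3 subjects per group")

    n = len(maps)
    if n != len(g) or n != len(ages):
        raise ValueError("design length does not match number of maps")
    affine = maps[0].affine
    data = np.stack([m.data for m in maps])          # (n, X, Y, Z)
    if any(m.data.shape != data.shape[1:] for m in maps):
        raise ValueError("all maps must share one grid")

    X = np.column_stack([np.ones(n), g, ages])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant age and group?)")
    p = X.shape[1]
    df = n - p

    defined = np.all(np.isfinite(data), axis=0)
    Y = data[:, defined]                              # (n, V)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    xtx_inv = np.linalg.inv(X.T @ X)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / df * xtx_inv[1, 1])
    # voxels fitted exactly (zero residual variance up to round-off) get
    # t = 0 for a zero group effect and a capped sentinel otherwise
    ss_tot = (Y**2).sum(axis=0) + 1e-300
    exact = rss < 1e-20 * ss_tot
    tvals = np.zeros_like(se)
    ok = (se > 0) & ~exact
    tvals[ok] = beta[1][ok] / se[ok]
    degen = exact & (np.abs(beta[1]) > 1e-8 * np.sqrt(ss_tot / n))
    tvals[degen] = np.sign(beta[1][degen]) * T_CAP

    t_map = np.full(data.shape[1:], np.nan)
    t_map[defined] = tvals
    resid_maps = np.full(data.shape, np.nan)
    resid_maps[:, defined] = resid
    return StatMap(t=t_map, df=df, defined=defined, affine=affine), resid_maps


def estimate_smoothness(resid_maps: np.ndarray, voxel_size: float
                        ) -> dict[str, float]:
    """Residual smoothness (FWHM, mm) from spatial first differences.

    Uses the Gaussian-random-field estimator: white noise convolved with a
    Gaussian kernel of sd s has autocorrelation rho(d) = exp(-d^2 / (4 s^2)),
    so the lag-1 autocorrelation rho = 1 - var(diff) / (2 var) of each
    residual map gives the kernel-equivalent smoothness
    FWHM = d * sqrt(2 ln 2 / (-ln rho)) per axis — the FWHM of the kernel
    that reproduces the residual autocorrelation when applied to white noise,
    matching the null-map generation of the Monte-Carlo calibration.  FWHM is
    floored at the voxel size (independent noise has rho ~ 0).
    """
    resid_maps = np.asarray(resid_maps, dtype=float)
    if resid_maps.ndim != 4 or resid_maps.shape[0] < 2:
        raise ValueError("need >= 2 residual maps (n, X, Y, Z)")
    fwhms = {ax: [] for ax in range(3)}
    any_var = False
    for r in resid_maps:
        vals = r[np.isfinite(r)]
        var = vals.var()
        if var == 0 or vals.size == 0:
            continue
        any_var = True
        for ax in range(3):
            d = np.diff(r, axis=ax)
            d = d[np.isfinite(d)]
            if d.size == 0:
                continue
            rho = 1.0 - d.var() / (2.0 * var)
            if rho <= 0:
                fw = voxel_size
            else:
                fw = voxel_size * np.sqrt(2 * np.log(2) / (-np.log(rho)))
            fwhms[ax].append(max(fw, voxel_size))
    if not any_var:
        raise ValueError("constant residuals: smoothness undefined")
    per_axis = [float(np.mean(fwhms[ax])) if fwhms[ax] else voxel_size
                for ax in range(3)]
    geo = float(np.exp(np.mean(np.log(per_axis))))
    return {"fwhm_x": per_axis[0], "fwhm_y": per_axis[1],
            "fwhm_z": per_axis[2], "fwhm": geo}


def montecarlo_cluster_threshold(shape: tuple[int, int, int], fwhm: float,
                                 voxel_size: float = 2.0,
                                 voxel_alpha: float = 1e-4,
                                 fw_alpha: float = 0.05,
                                 n_iter: int = 1000, seed: int = 0,
                                 connectivity: int = 26,
                                 metric: str = "") -> ClusterThreshold:
    """Calibrate the minimum cluster size by Monte-Carlo simulation.

    Simulates ``n_iter`` Gaussian null maps smoothed to ``fwhm``, thresholds
    two-sided at ``voxel_alpha`` and records the maximal suprathreshold
    cluster size; the threshold is the smallest k with
    P(max size >= k) <= fw_alpha.
    """
    if n_iter < 200:
        raise ValueError("n_iter must be >= 200 for a stable calibration")
    if fwhm < voxel_size - 1e-9:
        raise ValueError("fwhm below voxel size")
    rng = np.random.default_rng(seed)
    sigma_vox = 0.0
    if fwhm > voxel_size:
        sigma_vox = fwhm / (2.0 * np.sqrt(2 * np.log(2))) / voxel_size
    zc = stats.norm.isf(voxel_alpha / 2)
    structure = _connectivity_structure(connectivity)

    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        z = rng.standard_normal(shape)
        if sigma_vox > 0:
            z = ndimage.gaussian_filter(z, sigma_vox)
            z = z / z.std()
        supra = np.abs(z) > zc
        if not supra.any():
            continue
        lab, nlab = ndimage.label(supra, structure=structure)
        if nlab:
            max_sizes[i] = int(np.bincount(lab.ravel())[1:].max())

    # smallest k with exceedance probability <= fw_alpha
    srt = np.sort(max_sizes)
    k = 1
    while (srt >= k).mean() > fw_alpha:
        k += 1
    return ClusterThreshold(metric=metric, min_cluster_size=int(k),
                            voxel_alpha=voxel_alpha, fw_alpha=fw_alpha,
                            n_montecarlo=n_iter, fwhm_mm=float(fwhm),
                            seed=seed, max_size_distribution=max_sizes)


def permutation_cluster_threshold(maps: list[MetricVolume], groups: np.ndarray,
                                  ages: np.ndarray, voxel_alpha: float = 1e-4,
                                  fw_alpha: float = 0.05, n_perm: int = 500,
                                  seed: int = 0, connectivity: int = 26,
                                  metric: str = "") -> ClusterThreshold:
    """Calibrate the minimum cluster size by group-label permutation.

    Re-fits the voxelwise GLM under ``n_perm`` random permutations of the
    group labels (ages stay with their subjects) and records the maximal
    suprathreshold cluster size of each permuted t-map.  Unlike the Gaussian
    Monte-Carlo backend this matches the t-field's excursion geometry
    exactly, so it is not conservative at moderate degrees of freedom.
    """
    if n_perm < 200:
        raise ValueError("n_perm must be >= 200 for a stable calibration")
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    max_sizes = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(len(groups))
        stat, _ = voxelwise_glm(maps, groups[perm], ages)
        table = label_clusters(stat, voxel_alpha=voxel_alpha, min_size=1,
                               connectivity=connectivity)
        if len(table):
            max_sizes[i] = max(c.n_voxels for c in table.clusters)
    srt = np.sort(max_sizes)
    k = 1
    while (srt >= k).mean() > fw_alpha:
        k += 1
    return ClusterThreshold(metric=metric, min_cluster_size=int(k),
                            voxel_alpha=voxel_alpha, fw_alpha=fw_alpha,
                            n_montecarlo=n_perm, fwhm_mm=float("nan"),
                            seed=seed, max_size_distribution=max_sizes)


def label_clusters(statmap: StatMap, voxel_alpha: float = 1e-4,
                   min_size: int = 1, connectivity: int = 26,
                   metric: str = "") -> ClusterTable:
    """Connected suprathreshold components, sign-separated, size-filtered.

    Positive-t and negative-t voxels form separate components (signed t values
    are reported per cluster).  Components smaller than ``min_size`` voxels
    are discarded.  Centre = unweighted voxel mass centre rounded to the
    nearest voxel, reported in world mm; peak t keeps its sign.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    t_crit = stats.t.isf(voxel_alpha / 2, statmap.df)
    structure = _connectivity_structure(connectivity)
    voxel_vol = float(np.prod(np.linalg.norm(statmap.affine[:3, :3], axis=0)))

    table = ClusterTable(metric=metric)
    tt = np.where(statmap.defined, statmap.t, 0.0)
    for sign in (1, -1):
        supra = (sign * tt) > t_crit
        if not supra.any():
            continue
        lab, nlab = ndimage.label(supra, structure=structure)
        for li in range(1, nlab + 1):
            members = np.argwhere(lab == li)
            if len(members) < min_size:
                continue
            centre_vox = np.round(members.mean(axis=0))
            centre = (statmap.affine[:3, :3] @ centre_vox) + statmap.affine[:3, 3]
            tv = statmap.t[tuple(members.T)]
            peak = tv[np.argmax(np.abs(tv))]
            table.clusters.append(Cluster(
                members=members, volume_mm3=len(members) * voxel_vol,
                centre_world=centre, peak_t=float(peak)))
    table.clusters.sort(key=lambda c: -abs(c.peak_t))
    return table


def assign_atlas_labels(table: ClusterTable, atlas: np.ndarray,
                        names: dict[int, str], statmap: StatMap | None = None
                        ) -> ClusterTable:
    """Label each cluster with the modal atlas value over its member voxels.

    Ties are broken by the label covering the peak-|t| voxel (when a stat map
    is supplied, else by the smaller label id); clusters whose modal value is
    background (0) are labeled "unlabeled".
    """
    atlas = np.asarray(atlas)
    for c in table.clusters:
        vals = atlas[tuple(c.members.T)]
        counts = np.bincount(vals)
        top = counts.max()
        candidates = np.flatnonzero(counts == top)
        if len(candidates) > 1 and statmap is not None:
            tv = statmap.t[tuple(c.members.T)]
            peak_vox = c.members[np.argmax(np.abs(tv))]
            peak_label = atlas[tuple(peak_vox)]
            modal = peak_label if peak_label in candidates else candidates[0]
        else:
            modal = candidates[0]
        if modal == 0:
            c.label = "unlabeled"
        else:
            if int(modal) not in names:
                raise KeyError(f"no name for atlas label {int(modal)}")
            c.label = names[int(modal)]
    return table
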
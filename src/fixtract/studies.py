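"""Calibration and recovery studies exercising the pipeline end to end.

Each study builds its own inputs with the synthetic generator, runs the
method under test, and returns the measured quantities.  They are shared by
the validation suite and the reproduction script so both report numbers
computed the same way, from scratch, at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fixel import FixelField, MetricVolume, weighted_metric_map
from .synthetic import (BundleSpec, CohortConfig, EffectSpec, SubjectRecord,
                        build_phantom, default_bundles, default_clinical_model,
                        default_effects, metrics_from_eigenvalues,
                        simulate_clinical, simulate_subject,
                        simulate_tract_summaries)
from .clusters import (label_clusters, montecarlo_cluster_threshold,
                       permutation_cluster_threshold, voxelwise_glm)
from .tracking import Roi, TrackingParams, track_streamlines
from .tractometry import TractSampler, along_tract_profile, tract_mean_metric
from .stats import bh_fdr, bonferroni_gate, depression_model, welch_test


def _straight(name, axis, length, offset, radius=4.0,
              lambdas=(1.7e-3, 0.4e-3), fraction=0.5):
    t = np.linspace(0.0, length, 17)
    line = np.tile(np.asarray(offset, dtype=float), (17, 1))
    line[:, axis] = offset[axis] - length / 2 + t
    return BundleSpec(name, line, radius=radius,
                      baseline_metrics=metrics_from_eigenvalues(*lambdas),
                      fraction_profile=fraction)


def study_weighted_map(seed: int = 0, n_voxels: int = 10_000) -> dict:
    """Hand-checked weighted-map value plus identity errors on random voxels."""
    rng = np.random.default_rng(seed)
    ori = np.zeros((1, 1, 1, 2, 3))
    ori[..., 0] = 1.0
    fld = FixelField(np.eye(4), ori, np.array([[[[0.6, 0.2]]]]),
                     {"FA": np.array([[[[0.8, 0.5]]]])})
    worked = float(weighted_metric_map(fld, "FA").data[0, 0, 0])

    f = rng.dirichlet([1, 1, 1], size=n_voxels)[:, :2]
    m = rng.uniform(0, 1, size=(n_voxels, 2))

    def wm(fr, me):
        fl = FixelField(np.eye(4),
                        np.broadcast_to([1.0, 0, 0],
                                        (n_voxels, 1, 1, 2, 3)).copy(),
                        fr.reshape(n_voxels, 1, 1, 2),
                        {"FA": me.reshape(n_voxels, 1, 1, 2)})
        return weighted_metric_map(fl, "FA").data.ravel()

    base = wm(f, m)
    perm_err = float(np.abs(base - wm(f[:, ::-1], m[:, ::-1])).max())
    single_f = np.column_stack([f[:, 0], np.zeros(n_voxels)])
    single_err = float(np.abs(wm(single_f, m) - m[:, 0]).max())
    return {"worked_value": worked,
            "identity_max_error": max(perm_err, single_err),
            "n": n_voxels}


def crossing_phantom(a_lambdas=(1.7e-3, 0.4e-3), b_lambdas=(1.0e-3, 0.3e-3)):
    """Two orthogonal straight tubes crossing at the grid centre, zero noise."""
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(31, 31, 11),
                       voxel_size=2.0)
    centre = np.array([30.0, 30.0, 10.0])
    bundles = [_straight("along_x", 0, 48.0, centre, lambdas=a_lambdas,
                         fraction=0.5),
               _straight("along_y", 1, 48.0, centre, lambdas=b_lambdas,
                         fraction=0.4)]
    return build_phantom(cfg, bundles)


def study_crossing_specificity(seed: int = 0) -> dict:
    """Recover the straight bundle's AD (1.7e-3) through a 90-degree crossing
    with transverse AD 1.0e-3; angular weighting must fully exclude the
    orthogonal fixel."""
    ph = crossing_phantom()
    params = TrackingParams(n_seeds=800, max_streamlines=50, seed=seed)
    rois = [Roi(ph.rois["along_x"][r], r) for r in
            ("seed", "intermediary", "termination")]
    sset = track_streamlines(ph.field, rois, params)
    recovered = tract_mean_metric(sset, ph.field, "AD")
    return {"recovered_ad": float(recovered),
            "abs_error": float(abs(recovered - 1.7e-3)),
            "n": len(sset)}


def localization_phantom():
    """Two parallel straight 64 mm bundles (affected + control) on one grid."""
    cfg = CohortConfig(
        n_aud=20, n_control=20, grid_shape=(44, 13, 23), voxel_size=2.0,
        between_subject_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")})
    bundles = [_straight("affected", 0, 64.0, np.array([43.0, 12.0, 10.0])),
               _straight("control_tract", 0, 64.0,
                         np.array([43.0, 12.0, 34.0]))]
    return cfg, build_phantom(cfg, bundles)


def study_along_tract_localization(seed: int = 0, n_cohorts: int = 100
                                   ) -> dict:
    """A lesion in arc-length 37.5-62.5% must (i) depress exactly profile
    sections 4-5 in the noise-free subject and (ii) be flagged by
    Welch+Bonferroni on the affected tract only, across seeded cohorts
    (n = 20 + 20 per cohort, effect three times the voxel noise sd)."""
    cfg, ph = localization_phantom()
    magnitude = -3.0 * cfg.noise_sd["AD"]
    effects = [EffectSpec("affected", "AD", magnitude, section_range=(4, 5))]

    params = TrackingParams(n_seeds=1500, max_streamlines=60, seed=seed)
    samplers = {}
    for name in ("affected", "control_tract"):
        rois = [Roi(ph.rois[name][r], r) for r in
                ("seed", "intermediary", "termination")]
        sset = track_streamlines(ph.field, rois, params)
        samplers[name] = TractSampler(sset, ph.field)

    # (i) deterministic section localization on a noise-free subject
    clean_cfg = CohortConfig(
        n_aud=2, n_control=2,
        noise_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")},
        between_subject_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")})
    rec = SubjectRecord(id="s", group="AUD", session="E1", age=45.0, sex="M",
                       units_per_day=10.0, cnr=20.0)
    strong = [EffectSpec("affected", "AD", -0.4e-3, section_range=(4, 5))]
    lesioned = simulate_subject(ph, strong, rec, seed=seed, config=clean_cfg)
    profile = samplers["affected"].section_means(lesioned, "AD")
    depressed = set((np.flatnonzero(1.7e-3 - profile > 0.12e-3) + 1).tolist())
    sections_exact = float(depressed == {4, 5})

    # (ii) Welch + Bonferroni across seeded cohorts
    rng = np.random.default_rng(seed)
    n_correct = 0
    n_false = 0
    for _ in range(n_cohorts):
        means = {name: {"AUD": [], "control": []} for name in samplers}
        for group, n in (("AUD", cfg.n_aud), ("control", cfg.n_control)):
            for _i in range(n):
                r = SubjectRecord(id="x", group=group, session="E1", age=45.0,
                                 sex="M", units_per_day=10.0, cnr=20.0)
                fld = simulate_subject(ph, effects, r,
                                       seed=int(rng.integers(2**31)),
                                       config=cfg)
                for name, smp in samplers.items():
                    means[name][group].append(smp.mean(fld, "AD"))
        pvals = [welch_test(means[name]["AUD"], means[name]["control"]).p
                 for name in ("affected", "control_tract")]
        flags = bonferroni_gate(np.array(pvals), alpha=0.05)
        if flags[0] and not flags[1]:
            n_correct += 1
        if flags[1]:
            n_false += 1
    return {"sections_exact": sections_exact,
            "depressed_sections": sorted(depressed),
            "correct_flag_rate": n_correct / n_cohorts,
            "false_flag_rate": n_false / n_cohorts,
            "n": n_cohorts}


def study_cluster_fwe(seed: int = 0, n_cohorts: int = 200,
                      shape: tuple[int, int, int] = (40, 40, 40),
                      n_iter: int = 1000, n_per_group: int = 20,
                      fwhm: float = 6.0, n_perm: int = 500) -> dict:
    """Familywise error control of cluster-size thresholding on null data.

    Two routes, both at voxel alpha 1e-4 and familywise alpha 0.05 on a 40^3
    grid of 2 mm voxels with 6 mm smoothness:

    * Gaussian route — the Monte-Carlo threshold is validated on independent
      smoothed Gaussian null fields (the calibration's own null model).
    * Cohort route — a group-label permutation threshold (calibrated on one
      null cohort) is applied to fresh null cohorts of n = 20 + 20 smoothed
      noise maps run through the age-corrected voxelwise GLM; this matches
      the t-field's excursion geometry.
    """
    from scipy import ndimage
    from scipy import stats as _st

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
    n = 2 * n_per_group
    groups = np.array(["AUD"] * n_per_group + ["control"] * n_per_group)
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_cohorts)

    def smooth_map(rng):
        z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
        return z / z.std()

    # Gaussian route
    thr_mc = montecarlo_cluster_threshold(shape, fwhm=fwhm, voxel_size=2.0,
                                          voxel_alpha=1e-4, fw_alpha=0.05,
                                          n_iter=n_iter, seed=seed)
    rng = np.random.default_rng(seed + 1)
    zc = _st.norm.isf(1e-4 / 2)
    n_pos_gauss = 0
    for _ in range(n_cohorts):
        supra = np.abs(smooth_map(rng)) > zc
        if supra.any():
            lab, nlab = ndimage.label(supra, structure=np.ones((3, 3, 3)))
            if np.bincount(lab.ravel())[1:].max() >= thr_mc.min_cluster_size:
                n_pos_gauss += 1

    # cohort route: permutation calibration on one null cohort
    rng = np.random.default_rng(seed + 2)
    calib_maps = [MetricVolume(smooth_map(rng), affine) for _ in range(n)]
    calib_ages = rng.uniform(30, 65, n)
    thr_perm = permutation_cluster_threshold(calib_maps, groups, calib_ages,
                                             voxel_alpha=1e-4, fw_alpha=0.05,
                                             n_perm=n_perm, seed=seed + 3)
    n_pos_cohort = 0
    for _ in range(n_cohorts):
        maps = [MetricVolume(smooth_map(rng), affine) for _ in range(n)]
        ages = rng.uniform(30, 65, n)
        stat, _ = voxelwise_glm(maps, groups, ages)
        table = label_clusters(stat, voxel_alpha=1e-4,
                               min_size=thr_perm.min_cluster_size)
        if len(table):
            n_pos_cohort += 1

    return {"fwe_rate_gaussian_null": n_pos_gauss / n_cohorts,
            "fwe_rate_cohort_null": n_pos_cohort / n_cohorts,
            "mc_min_cluster_size": thr_mc.min_cluster_size,
            "perm_min_cluster_size": thr_perm.min_cluster_size,
            "ci_low": 0.05 - half, "ci_high": 0.05 + half, "n": n_cohorts}


def study_residualization(seed: int = 0) -> dict:
    """Residualization contracts on a generated tract table."""
    from .tractometry import residualize_cnr
    rng = np.random.default_rng(seed)
    rows = []
    for tract in ("cingulum", "uncinate"):
        for metric in ("FA", "AD"):
            cnr = rng.uniform(10, 30, 40)
            val = 1.0 + 0.02 * cnr + rng.normal(0, 0.1, 40)
            for c, v in zip(cnr, val):
                rows.append(dict(tract=tract, metric=metric, cnr=c, value=v))
    out = residualize_cnr(pd.DataFrame(rows))
    max_corr, max_mean = 0.0, 0.0
    for _, sub in out.groupby(["tract", "metric"]):
        r = sub["value_resid"].to_numpy()
        max_corr = max(max_corr, abs(np.corrcoef(r, sub["cnr"])[0, 1]))
        max_mean = max(max_mean, abs(r.mean()))

    exact = pd.DataFrame({"tract": "t", "metric": "FA",
                          "cnr": np.linspace(10, 30, 20),
                          "value": 2.0 + 3.0 * np.linspace(10, 30, 20)})
    exact_resid = float(np.abs(residualize_cnr(exact)["value_resid"]).max())
    return {"max_abs_correlation": float(max_corr),
            "max_abs_mean": float(max_mean),
            "exact_linear_max_resid": exact_resid, "n": len(out)}


def bh_bruteforce(pvals: np.ndarray, q: float) -> np.ndarray:
    """Independent step-up oracle: largest k with p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(m, 0, -1):
        if p[order[i - 1]] <= i * q / m:
            k = i
            break
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    return flags


def study_bh_and_welch_null(seed: int = 0, n_vectors: int = 1000,
                            n_reps: int = 2000) -> dict:
    """BH equals the brute-force oracle on random p-vectors; Welch null
    p-values pass a Kolmogorov-Smirnov uniformity check."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 13))
        p = rng.uniform(0, 1, m)
        q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
        flags, _ = bh_fdr(p, q)
        if np.array_equal(flags, bh_bruteforce(p, q)):
            agree += 1
    pvals = [welch_test(rng.normal(0, 1, 40), rng.normal(0, 3, 25)).p
             for _ in range(n_reps)]
    ks_p = float(sps.kstest(pvals, "uniform").pvalue)
    return {"bh_agreement_rate": agree / n_vectors, "welch_ks_pvalue": ks_p,
            "n": n_vectors}


def study_clinical_recovery(seed: int = 0, n_cohorts: int = 100,
                            n_per_group: int = 20) -> dict:
    """Sign recovery of the planted depression model across seeded cohorts.

    Lower FA on the designated tract and higher RD on another raise BDI;
    group and time main effects are planted alongside.  Success requires the
    fitted model to recover all four coefficient signs.
    """
    bundles = default_bundles()
    effects = default_effects()
    model = default_clinical_model(fa_tract="cingulum", rd_tract="uncinate")
    rng = np.random.default_rng(seed)
    n_recovered = 0
    for _ in range(n_cohorts):
        rows = []
        for g, n, tag in (("AUD", n_per_group, "aud"),
                          ("control", n_per_group, "ctl")):
            for i in range(n):
                cnr = max(rng.normal(20, 4), 1.0)
                for s in ("E1", "E2"):
                    rows.append(dict(id=f"{tag}{i}", group=g, session=s,
                                     age=50.0, sex="M", units_per_day=10.0,
                                     cnr=cnr, bdi=np.nan, ocds=np.nan,
                                     sai=np.nan))
        records = pd.DataFrame(rows)
        cfg = CohortConfig(n_aud=n_per_group, n_control=n_per_group)
        summ = simulate_tract_summaries(cfg, bundles, effects, records,
                                        seed=int(rng.integers(2**31)))
        scored = simulate_clinical(records, summ, model,
                                   seed=int(rng.integers(2**31)),
                                   clip_to_range=False)
        wide = summ.pivot_table(index=["subject", "session"],
                                columns=["tract", "metric"], values="value")
        wide.columns = [f"{t}_{m}" for t, m in wide.columns]
        merged = scored.set_index(["id", "session"]).join(
            wide.rename_axis(["id", "session"])).reset_index()
        res = depression_model(merged, ["cingulum_FA", "uncinate_RD"],
                               mixed=True)
        coef = res.coefficients.set_index("name")["B"]
        ok = (coef["group"] < 0          # controls coded 1, patients higher
              and coef["time"] < 0
              and coef["cingulum_FA"] < 0
              and coef["uncinate_RD"] > 0)
        n_recovered += bool(ok)
    return {"sign_recovery_rate": n_recovered / n_cohorts, "n": n_cohorts}


def study_vif(seed: int = 0, n: int = 400) -> dict:
    """VIF of an orthogonalized design and of a constructed r = 0.9 pair."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 2))
    q, _ = np.linalg.qr(base - base.mean(0))
    tab = pd.DataFrame(dict(
        id=[f"s{i}" for i in range(n)],
        group=["AUD"] * (n // 2) + ["control"] * (n // 2),
        session=["E1", "E2"] * (n // 2),
        bdi=rng.normal(20, 5, n), m1=q[:, 0], m2=q[:, 1]))
    res_orth = depression_model(tab, ["m1", "m2"], mixed=False)

    # pair with empirical correlation exactly 0.9: mix two orthonormal
    # columns so the sample statistics match the construction
    r = 0.9
    q2, _ = np.linalg.qr(rng.normal(size=(n, 2)) - 0.0)
    u1 = (q2[:, 0] - q2[:, 0].mean())
    u2 = (q2[:, 1] - q2[:, 1].mean())
    u2 -= u1 * (u1 @ u2) / (u1 @ u1)
    u1 /= np.linalg.norm(u1)
    u2 /= np.linalg.norm(u2)
    x1 = u1
    x2 = r * u1 + np.sqrt(1 - r**2) * u2
    tab2 = tab.copy()
    tab2["m1"], tab2["m2"] = x1, x2
    res_coll = depression_model(tab2, ["m1", "m2"], mixed=False)
    emp_r = float(np.corrcoef(x1, x2)[0, 1])
    return {"vif_orthogonal_max": float(max(res_orth.vif["m1"],
                                            res_orth.vif["m2"])),
            "vif_collinear": float(res_coll.vif["m1"]),
            "vif_collinear_expected": 1.0 / (1.0 - emp_r**2),
            "n": n}


def study_weighted_mean_consumption() -> dict:
    """Pool the sex-specific daily-consumption means (18.9 units for 42 men,
    11.36 units for 11 women) into the cohort mean."""
    from .stats import weighted_mean
    value = weighted_mean([18.9, 11.36], [42, 11])
    return {"cohort_mean_units_per_day": round(value, 2), "n": 53}
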
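"""Synthetic cohort generator: phantom construction, effects, clinical model."""

import numpy as np
import pandas as pd
import pytest

from fixtract.synthetic import (BundleSpec, ClinicalModel, CohortConfig,
                                EffectSpec, SubjectRecord, build_phantom,
                                default_bundles, default_effects,
                                generate_cohort, metrics_from_eigenvalues,
                                simulate_clinical, simulate_subject,
                                simulate_tract_summaries)
from tests.conftest import straight_bundle


def test_tensor_metrics_internally_consistent():
    m = metrics_from_eigenvalues(1.7e-3, 0.4e-3)
    assert m["MD"] == pytest.approx((m["AD"] + 2 * m["RD"]) / 3, abs=1e-15)
    fa = (m["AD"] - m["RD"]) / np.sqrt(m["AD"]**2 + 2 * m["RD"]**2)
    assert m["FA"] == pytest.approx(fa, abs=1e-12)
    with pytest.raises(ValueError):
        metrics_from_eigenvalues(0.4e-3, 1.7e-3)


def test_bundle_spec_rejects_inconsistent_metrics():
    line = np.array([[0, 0, 0], [10, 0, 0.0]])
    good = metrics_from_eigenvalues(1.7e-3, 0.4e-3)
    BundleSpec("ok", line, 2.0, good)
    bad = dict(good, MD=good["MD"] * 1.1)
    with pytest.raises(ValueError):
        BundleSpec("bad", line, 2.0, bad)


def test_straight_bundle_rasterization():
    """Every in-bundle voxel carries the tangent orientation and the
    configured fraction; the isotropic compartment closes the budget."""
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(21, 9, 9))
    b = straight_bundle("b", 0, 30.0, np.array([20.0, 8.0, 8.0]),
                        fraction=0.6)
    ph = build_phantom(cfg, [b])
    bv = ph.membership["b"]
    assert len(bv.indices) > 0
    for idx, slot in zip(bv.indices, bv.slots):
        u = ph.field.orientations[tuple(idx) + (slot,)]
        np.testing.assert_allclose(np.abs(u), [1, 0, 0], atol=1e-12)
        assert ph.field.fractions[tuple(idx) + (slot,)] == pytest.approx(0.6)
        assert ph.field.f_iso[tuple(idx)] == pytest.approx(0.4)


def test_crossing_voxels_carry_two_fixels(crossing_phantom):
    ph, _ = crossing_phantom
    both = (ph.field.fractions > 0).sum(axis=3) == 2
    assert both.any()
    ii = np.argwhere(both)[0]
    u1, u2 = ph.field.orientations[tuple(ii)]
    assert abs(u1 @ u2) < 1e-9          # orthogonal crossing


def test_fraction_closure_everywhere(crossing_phantom):
    ph, _ = crossing_phantom
    total = ph.field.fractions.sum(axis=3) + ph.field.f_iso
    np.testing.assert_allclose(total, 1.0, atol=1e-9)


def test_empty_bundle_list_gives_pure_isotropic():
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(8, 8, 8))
    ph = build_phantom(cfg, [])
    assert np.all(ph.field.f_iso == 1.0)
    assert np.all(ph.field.fractions == 0.0)


def test_three_way_overlap_rejected():
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(15, 15, 15))
    c = np.array([14.0, 14.0, 14.0])
    bundles = [straight_bundle("a", 0, 20.0, c, fraction=0.3),
               straight_bundle("b", 1, 20.0, c, fraction=0.3),
               straight_bundle("c", 2, 20.0, c, fraction=0.3)]
    with pytest.raises(ValueError, match="overlap"):
        build_phantom(cfg, bundles)


def test_centerline_outside_grid_rejected():
    cfg = CohortConfig(n_aud=2, n_control=2, grid_shape=(10, 10, 10))
    line = np.array([[0, 0, 0], [100.0, 0, 0]])
    b = BundleSpec("out", line, 2.0, metrics_from_eigenvalues(1.7e-3, 0.4e-3))
    with pytest.raises(ValueError, match="grid"):
        build_phantom(cfg, [b])


def test_rois_nonempty_and_disjoint_roles(single_bundle_phantom):
    ph, _ = single_bundle_phantom
    rois = ph.rois["bundle"]
    for role in ("seed", "intermediary", "termination"):
        assert rois[role].sum() >= 2
    assert not (rois["seed"] & rois["termination"]).any()


def _record(group="AUD", session="E1", cnr=20.0):
    return SubjectRecord(id="s1", group=group, session=session, age=45.0,
                        sex="M", units_per_day=15.0, cnr=cnr)


def test_simulate_subject_identity_and_effects(single_bundle_phantom):
    ph, bundle = single_bundle_phantom
    cfg = CohortConfig(n_aud=2, n_control=2,
                       noise_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")})

    clean = simulate_subject(ph, [], _record(), seed=0, config=cfg)
    np.testing.assert_array_equal(clean.metrics["AD"], ph.field.metrics["AD"])

    eff = EffectSpec("bundle", "AD", -0.1e-3, section_range="whole")
    shifted = simulate_subject(ph, [eff], _record(), seed=0, config=cfg)
    bv = ph.membership["bundle"]
    sub = tuple(bv.indices.T) + (bv.slots,)
    np.testing.assert_allclose(shifted.metrics["AD"][sub],
                               ph.field.metrics["AD"][sub] - 0.1e-3,
                               atol=1e-15)
    # control subjects are untouched
    ctl = simulate_subject(ph, [eff], _record(group="control"), seed=0,
                           config=cfg)
    np.testing.assert_array_equal(ctl.metrics["AD"], ph.field.metrics["AD"])


def test_simulate_subject_sectioned_effect(single_bundle_phantom):
    ph, _ = single_bundle_phantom
    cfg = CohortConfig(n_aud=2, n_control=2,
                       noise_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")})
    eff = EffectSpec("bundle", "AD", -0.2e-3, section_range=(4, 5))
    out = simulate_subject(ph, [eff], _record(), seed=0, config=cfg)
    bv = ph.membership["bundle"]
    sec = bv.section_of()
    sub = tuple(bv.indices.T) + (bv.slots,)
    delta = out.metrics["AD"][sub] - ph.field.metrics["AD"][sub]
    assert np.allclose(delta[np.isin(sec, (4, 5))], -0.2e-3)
    assert np.allclose(delta[~np.isin(sec, (4, 5))], 0.0)


def test_simulate_subject_determinism(single_bundle_phantom):
    ph, _ = single_bundle_phantom
    cfg = CohortConfig(n_aud=2, n_control=2)
    a = simulate_subject(ph, [], _record(), seed=7, config=cfg)
    b = simulate_subject(ph, [], _record(), seed=7, config=cfg)
    c = simulate_subject(ph, [], _record(), seed=8, config=cfg)
    np.testing.assert_array_equal(a.metrics["FA"], b.metrics["FA"])
    assert not np.array_equal(a.metrics["FA"], c.metrics["FA"])


def test_simulate_subject_unknown_bundle_errors(single_bundle_phantom):
    ph, _ = single_bundle_phantom
    cfg = CohortConfig(n_aud=2, n_control=2)
    with pytest.raises(KeyError):
        simulate_subject(ph, [EffectSpec("nope", "AD", -1e-4)], _record(),
                         seed=0, config=cfg)


def _records_frame(n_aud=5, n_ctl=5):
    rows = []
    for g, n, tag in (("AUD", n_aud, "aud"), ("control", n_ctl, "ctl")):
        for i in range(n):
            for s in ("E1", "E2"):
                rows.append(dict(id=f"{tag}{i}", group=g, session=s, age=50.0,
                                 sex="M", units_per_day=10.0, cnr=20.0,
                                 bdi=np.nan, ocds=np.nan, sai=np.nan))
    return pd.DataFrame(rows)


def test_clinical_intercept_only():
    model = ClinicalModel(intercepts={"bdi": 5.4}, beta_group={"bdi": 0.0},
                          beta_time={"bdi": 0.0}, residual_sd={"bdi": 0.0})
    out = simulate_clinical(_records_frame(), None, model, seed=0)
    assert np.allclose(out["bdi"], 5.4)


def test_clinical_group_contrast_exact():
    model = ClinicalModel(intercepts={"bdi": 5.4}, beta_group={"bdi": 17.0},
                          beta_time={"bdi": 0.0}, residual_sd={"bdi": 0.0})
    out = simulate_clinical(_records_frame(), None, model, seed=0)
    diff = (out[out.group == "AUD"]["bdi"].mean()
            - out[out.group == "control"]["bdi"].mean())
    assert diff == pytest.approx(17.0, abs=1e-12)


def test_clinical_planted_fa_correlation_negative():
    """A planted negative FA coefficient yields a negative sample correlation."""
    cfg = CohortConfig(n_aud=30, n_control=30, seed=3)
    bundles = default_bundles()
    recs = _records_frame(30, 30)
    summ = simulate_tract_summaries(cfg, bundles, default_effects(), recs,
                                    seed=3)
    model = ClinicalModel(intercepts={"bdi": 20.0}, beta_group={"bdi": 0.0},
                          beta_time={"bdi": 0.0}, residual_sd={"bdi": 1.0},
                          metric_betas={"bdi": [("cingulum", "FA", -200.0)]})
    out = simulate_clinical(recs, summ, model, seed=4)
    fa = summ[(summ.tract == "cingulum") & (summ.metric == "FA")]
    merged = out.merge(fa, left_on=["id", "session"],
                       right_on=["subject", "session"])
    assert np.corrcoef(merged["bdi"], merged["value"])[0, 1] < 0


def test_clinical_missing_summary_errors():
    model = ClinicalModel(metric_betas={"bdi": [("ghost", "FA", -1.0)]})
    with pytest.raises(KeyError):
        simulate_clinical(_records_frame(), None, model, seed=0)


def test_clinical_scores_within_instrument_ranges():
    cohort = generate_cohort(CohortConfig(n_aud=10, n_control=5,
                                          grid_shape=(12, 12, 12), seed=1),
                             [], [])
    r = cohort.records
    assert r["bdi"].between(0, 63).all()
    assert r["sai"].between(20, 80).all()
    assert (r["ocds"] >= 0).all()


def test_cohort_reproducibility_and_truth_ledger():
    cfg = dict(n_aud=3, n_control=3, grid_shape=(20, 20, 20), seed=11)
    bundles = default_bundles((20, 20, 20))
    effects = default_effects()
    c1 = generate_cohort(CohortConfig(**cfg), bundles, effects)
    c2 = generate_cohort(CohortConfig(**cfg), bundles, effects)
    pd.testing.assert_frame_equal(c1.records, c2.records)
    f1 = c1.field("aud001", "E1")
    f2 = c2.field("aud001", "E1")
    np.testing.assert_array_equal(f1.metrics["AD"], f2.metrics["AD"])

    # the truth ledger records every planted effect
    assert len(c1.truth["effects"]) == len(effects)
    assert {e["bundle_name"] for e in c1.truth["effects"]} <= set(
        c1.phantom.membership)


def test_session_correlation_induces_within_subject_similarity():
    """Correlated session noise: E1 and E2 of one subject agree more than
    two different subjects do."""
    cfg = CohortConfig(n_aud=4, n_control=2, grid_shape=(24, 24, 24),
                       session_correlation=0.9, seed=5,
                       between_subject_sd={m: 0.0 for m in ("FA", "AD", "RD", "MD")})
    bundles = default_bundles((24, 24, 24))
    cohort = generate_cohort(cfg, bundles, [])
    act = cohort.phantom.field.fractions > 0

    def dev(sid, ses):
        f = cohort.field(sid, ses)
        return (f.metrics["FA"] - cohort.phantom.field.metrics["FA"])[act]

    within = np.corrcoef(dev("aud001", "E1"), dev("aud001", "E2"))[0, 1]
    across = np.corrcoef(dev("aud001", "E1"), dev("aud002", "E1"))[0, 1]
    assert within > 0.5 > abs(across)
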
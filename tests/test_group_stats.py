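"""Welch tests, multiple-comparison procedures, and the clinical models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fixtract.stats import (bh_fdr, bonferroni_gate, consumption_regression,
                            depression_model, longitudinal_fixed_model,
                            normality_gated_correlation, weighted_mean,
                            welch_test)


# ---------------------------------------------------------------------------
# Welch
# ---------------------------------------------------------------------------

def test_welch_hand_computed_example():
    res = welch_test([1.0, 2, 3], [2.0, 3, 4])
    assert res.statistic == pytest.approx(-1.224744871, abs=1e-6)
    assert res.df == pytest.approx(4.0, abs=1e-9)
    assert res.p == pytest.approx(0.2879, abs=2e-4)


def test_welch_identical_and_degenerate():
    res = welch_test([1.0, 2, 3], [1.0, 2, 3])
    assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    res = welch_test([5.0, 5, 5], [5.0, 5, 5, 5])
    assert res.p == 1.0                   # equal constants convention

    with pytest.raises(ValueError):
        welch_test([5.0, 5], [7.0, 7])    # unequal constants
    with pytest.raises(ValueError):
        welch_test([1.0], [1.0, 2.0])


def test_welch_reduces_to_student_under_equal_n_and_variance():
    a = np.array([1.0, 2, 3, 4, 5])
    b = a + 0.8                            # same sample variance, equal n
    w = welch_test(a, b)
    s = sps.ttest_ind(a, b, equal_var=True)
    assert w.statistic == pytest.approx(s.statistic, abs=1e-12)
    assert w.df == pytest.approx(len(a) + len(b) - 2, abs=1e-9)


def test_welch_df_bounds_property():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.normal(0, 1, rng.integers(3, 12))
        b = rng.normal(0, 3, rng.integers(3, 12))
        res = welch_test(a, b)
        assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2
        assert 0 <= res.p <= 1


def test_welch_null_uniformity_ks():
    """Null Welch p-values are Uniform(0,1) under unequal variances."""
    rng = np.random.default_rng(1)
    pvals = [welch_test(rng.normal(0, 1, 40), rng.normal(0, 3, 25)).p
             for _ in range(2000)]
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# multiple comparisons
# ---------------------------------------------------------------------------

def test_bonferroni_examples():
    assert bonferroni_gate([0.04]).tolist() == [True]
    m20 = [0.004] + [0.5] * 19
    assert bonferroni_gate(m20).tolist() == [False] + [False] * 19  # 0.004>0.0025
    assert bonferroni_gate([0.0] * 7).all()
    assert bonferroni_gate([0.03, 0.5], alpha=0.05).tolist() == [False, False]


def _bh_bruteforce(pvals, q):
    """Independent oracle: scan k from m down for p_(k) <= k q / m."""
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


def test_bh_worked_example():
    flags, crit = bh_fdr([0.001, 0.02, 0.03, 0.9], q=0.05)
    assert flags.tolist() == [True, True, True, False]
    np.testing.assert_allclose(crit, [0.0125, 0.025, 0.0375, 0.05])


def test_bh_edge_cases():
    flags, _ = bh_fdr([1.0, 1.0, 1.0])
    assert not flags.any()
    flags, crit = bh_fdr([0.04], q=0.05)
    assert flags.tolist() == [True] and crit[0] == pytest.approx(0.05)


def test_bh_matches_bruteforce_and_statsmodels():
    """Exhaustive agreement with a brute-force oracle (and statsmodels) on
    1000 random p-vectors of length <= 12."""
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(2)
    for _ in range(1000):
        m = int(rng.integers(1, 13))
        p = rng.uniform(0, 1, m)
        if rng.random() < 0.3:
            p[rng.integers(m)] = p[rng.integers(m)]   # ties
        q = float(rng.choice([0.01, 0.05, 0.1, 0.25]))
        flags, _ = bh_fdr(p, q)
        np.testing.assert_array_equal(flags, _bh_bruteforce(p, q))
        sm_flags = multipletests(p, alpha=q, method="fdr_bh")[0]
        np.testing.assert_array_equal(flags, sm_flags)


# ---------------------------------------------------------------------------
# normality-gated correlation
# ---------------------------------------------------------------------------

def test_gated_correlation_routes():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    y = 2 * x + rng.normal(0, 0.1, 60)
    res = normality_gated_correlation(x, y)
    assert res.method == "pearson" and res.statistic > 0.95

    xh = rng.standard_cauchy(60)
    yh = xh**3                             # monotone nonlinear, heavy-tailed
    res = normality_gated_correlation(xh, yh)
    assert res.method == "spearman"
    assert res.statistic == pytest.approx(1.0, abs=1e-12)

    with pytest.raises(ValueError):
        normality_gated_correlation(np.ones(10), rng.normal(size=10))
    with pytest.raises(ValueError):
        normality_gated_correlation([1.0, 2, 3], [1.0, 2, 4])  # n < 4


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _longitudinal_table(delta_group=0.5, delta_time=0.0, noise=0.0, n=8,
                        seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("AUD", "control"):
        for i in range(n):
            for s in ("E1", "E2"):
                v = (1.0 + delta_group * (g == "AUD")
                     + delta_time * (s == "E2") + rng.normal(0, noise))
                rows.append(dict(id=f"{g}{i}", group=g, session=s, value=v))
    return pd.DataFrame(rows)


def test_longitudinal_exact_recovery():
    res = longitudinal_fixed_model(_longitudinal_table(0.5, -0.2))
    coef = res.coefficients.set_index("name")
    assert coef.loc["group", "B"] == pytest.approx(0.5, abs=1e-10)
    assert coef.loc["time", "B"] == pytest.approx(-0.2, abs=1e-10)
    assert coef.loc["intercept", "B"] == pytest.approx(1.0, abs=1e-10)


def test_longitudinal_balanced_equals_cell_contrasts():
    tab = _longitudinal_table(0.3, 0.1, noise=0.2, seed=4)
    res = longitudinal_fixed_model(tab)
    coef = res.coefficients.set_index("name")
    cells = tab.groupby(["group", "session"])["value"].mean()
    g_contrast = cells["AUD"].mean() - cells["control"].mean()
    t_contrast = (cells.xs("E2", level=1).mean()
                  - cells.xs("E1", level=1).mean())
    assert coef.loc["group", "B"] == pytest.approx(g_contrast, abs=1e-10)
    assert coef.loc["time", "B"] == pytest.approx(t_contrast, abs=1e-10)


def test_longitudinal_time_only_group_null():
    res = longitudinal_fixed_model(_longitudinal_table(0.0, 0.4, noise=0.1,
                                                       seed=5))
    coef = res.coefficients.set_index("name")
    assert abs(coef.loc["group", "B"]) < 3 * coef.loc["group", "SE"]


def test_longitudinal_missing_cell_errors():
    tab = _longitudinal_table()
    tab = tab[~((tab.group == "AUD") & (tab.session == "E2"))]
    with pytest.raises(ValueError):
        longitudinal_fixed_model(tab)


def _clinical_table(beta_group=-15.0, noise=0.0, n=20, seed=0,
                    collinear=False):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("AUD", "control"):
        for i in range(n):
            m1, m2 = rng.normal(size=2)
            m3 = 0.9 * m1 + np.sqrt(1 - 0.81) * rng.normal() if collinear \
                else rng.normal()
            for s in ("E1", "E2"):
                bdi = 20.0 + beta_group * (g == "control") + rng.normal(0, noise)
                rows.append(dict(id=f"{g}{i}", group=g, session=s, bdi=bdi,
                                 m1=m1, m2=m2, m3=m3))
    return pd.DataFrame(rows)


def test_depression_model_recovers_group_effect():
    tab = _clinical_table(beta_group=-15.0, noise=0.0)
    res = depression_model(tab, ["m1", "m2"], mixed=False)
    coef = res.coefficients.set_index("name")
    assert coef.loc["group", "B"] == pytest.approx(-15.0, abs=1e-8)


def test_depression_model_vif_orthogonal_and_collinear():
    rng = np.random.default_rng(7)
    n = 64
    base = rng.normal(size=(n, 2))
    q, _ = np.linalg.qr(base - base.mean(0))
    tab = pd.DataFrame(dict(
        id=[f"s{i}" for i in range(n)],
        group=["AUD"] * (n // 2) + ["control"] * (n // 2),
        session=["E1", "E2"] * (n // 2),
        bdi=rng.normal(20, 5, n), m1=q[:, 0], m2=q[:, 1]))
    # force orthogonality to group/time as well: VIF ~ 1
    res = depression_model(tab, ["m1", "m2"], mixed=False)
    assert res.vif["m1"] < 1.2 and res.vif["m2"] < 1.2

    tab2 = _clinical_table(noise=5.0, collinear=True, seed=8, n=200)
    res2 = depression_model(tab2, ["m1", "m2", "m3"], mixed=False)
    r = np.corrcoef(tab2["m1"], tab2["m3"])[0, 1]
    expect = 1.0 / (1.0 - r**2)
    assert res2.vif["m1"] == pytest.approx(expect, rel=0.05)
    assert res2.vif["m2"] < 1.2


def test_depression_model_mixed_agrees_with_ols_when_no_subject_variance():
    tab = _clinical_table(beta_group=-10.0, noise=2.0, seed=9, n=30)
    ols = depression_model(tab, ["m1"], mixed=False)
    mix = depression_model(tab, ["m1"], mixed=True)
    b_ols = ols.coefficients.set_index("name")["B"]
    b_mix = mix.coefficients.set_index("name")["B"]
    np.testing.assert_allclose(b_mix, b_ols, atol=0.2)


def test_consumption_regression_exact_and_flags():
    rng = np.random.default_rng(10)
    rows = []
    for i in range(12):
        units = float(rng.uniform(2, 30))
        for s in ("E1", "E2"):
            rows.append(dict(id=f"s{i}", session=s, tract="cingulum",
                             metric="AD", units_per_day=units,
                             value=2.0 + 0.1 * units + 0.5 * (s == "E2")))
            rows.append(dict(id=f"s{i}", session=s, tract="fornix",
                             metric="AD", units_per_day=units,
                             value=float(rng.normal())))
    out = consumption_regression(pd.DataFrame(rows))
    e1 = out[(out.tract == "cingulum") & (out.target == "E1")]
    assert e1["R"].iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert e1["significant"].iloc[0]
    delta = out[(out.tract == "cingulum") & (out.target == "delta")]
    assert abs(delta["R"].iloc[0]) < 1.0     # constant shift: no delta link

    bad = pd.DataFrame(rows)
    bad["units_per_day"] = 5.0
    with pytest.raises(ValueError):
        consumption_regression(bad)


def test_weighted_mean_reported_cohort_consumption():
    """The sex-specific consumption means (18.9 units, n=42; 11.36 units,
    n=11) pool to 17.34 units/day."""
    assert weighted_mean([18.9, 11.36], [42, 11]) == pytest.approx(17.34,
                                                                   abs=0.005)
    assert weighted_mean([4.2], [7]) == pytest.approx(4.2)
    assert weighted_mean([1.0, 3.0], [5, 5]) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        weighted_mean([1.0], [0])
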
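"""The study's statistical battery.

Group comparisons of tract metrics use Welch's t-test (unequal variances and
sample sizes) with Bonferroni correction of the significance level.
Brain-behaviour correlations use Pearson's r when both variables pass a
Shapiro-Wilk normality check and Spearman's rho otherwise, with
Benjamini-Hochberg control of the false discovery rate (the per-rank critical
values i*q/m are reported alongside p).  Longitudinal effects are evaluated
with fixed-effects linear models (group + time main effects); the depression
model regresses BDI on group, time and mean-centred tract metrics with a
subject random intercept (REML), screening the fixed design for
multicollinearity via variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    n: tuple[int, ...]
    method: str


@dataclass
class ModelResult:
    coefficients: pd.DataFrame          # name, B, SE, t, p
    vif: dict[str, float] = field(default_factory=dict)
    random_intercept_var: float | None = None
    n_obs: int = 0
    method: str = "ols"
    warnings: list[str] = field(default_factory=list)

    @property
    def high_vif(self) -> list[str]:
        return [k for k, v in self.vif.items() if v >= 10]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def welch_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Welch's two-sample t-test (Satterthwaite df), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # degenerate: identical constants; keep simulation loops total
            return TestResult(0.0, float(len(a) + len(b) - 2), 1.0,
                              (len(a), len(b)), "welch")
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      (len(a), len(b)), "welch")


def bonferroni_gate(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected level alpha/m."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value family")
    return pvals < alpha / pvals.size


def normality_gated_correlation(x: np.ndarray, y: np.ndarray,
                                alpha_norm: float = 0.05) -> TestResult:
    """Pearson if both variables pass Shapiro-Wilk at alpha_norm, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    normal = (sps.shapiro(x).pvalue > alpha_norm
              and sps.shapiro(y).pvalue > alpha_norm)
    if normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return TestResult(float(r), float(len(x) - 2), float(p),
                      (len(x),), method)


def bh_fdr(pvals: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (flags, critical) where critical[i] is the rank critical value
    i*q/m of p_i's ascending rank, and flags marks the first k order
    statistics with k = max{i : p_(i) <= i*q/m}.
    """
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if m == 0:
        raise ValueError("empty p-value family")
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    crit_sorted = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(ranked <= crit_sorted)
    k = passing[-1] + 1 if passing.size else 0
    flags = np.zeros(m, dtype=bool)
    flags[order[:k]] = True
    critical = np.empty(m)
    critical[order] = crit_sorted
    return flags, critical


def weighted_mean(means: np.ndarray, counts: np.ndarray) -> float:
    """Count-weighted mean of subgroup means."""
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 1) or counts.sum() == 0:
        raise ValueError("counts must be >= 1 with positive total")
    return float((means * counts).sum() / counts.sum())


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _coef_frame(names: list[str], params: np.ndarray, bse: np.ndarray,
                tvals: np.ndarray, pvals: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"name": names, "B": params, "SE": bse,
                         "t": tvals, "p": pvals})


def _vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors, intercept included in auxiliary fits."""
    out = {}
    Xc = sm.add_constant(X, has_constant="add")
    arr = Xc.to_numpy(float)
    for j, name in enumerate(Xc.columns):
        if name == "const":
            continue
        others = np.delete(arr, j, axis=1)
        r2 = sm.OLS(arr[:, j], others).fit().rsquared
        out[name] = float(np.inf if r2 >= 1 else 1.0 / (1.0 - r2))
    return out


def longitudinal_fixed_model(table: pd.DataFrame, value_col: str = "value",
                             group_col: str = "group",
                             session_col: str = "session") -> ModelResult:
    """OLS of a tract metric on {intercept, group, time} main effects.

    Group is coded 1 for AUD, time 1 for the second session; no interaction,
    matching the longitudinal fixed-effects analysis.
    """
    groups = sorted(table[group_col].unique())
    sessions = sorted(table[session_col].unique())
    if len(groups) != 2 or len(sessions) != 2:
        raise ValueError("need exactly two groups and two sessions")
    cells = table.groupby([group_col, session_col]).size()
    if len(cells) < 4:
        raise ValueError("missing group x session cell")
    g = (table[group_col] == ("AUD" if "AUD" in groups else groups[-1])).astype(float)
    t = (table[session_col] == sessions[-1]).astype(float)
    X = pd.DataFrame({"group": g.to_numpy(), "time": t.to_numpy()})
    fit = sm.OLS(table[value_col].to_numpy(float),
                 sm.add_constant(X)).fit()
    names = ["intercept", "group", "time"]
    return ModelResult(
        coefficients=_coef_frame(names, fit.params, fit.bse,
                                 fit.tvalues, fit.pvalues),
        vif=_vif(X), n_obs=int(fit.nobs), method="ols")


def depression_model(table: pd.DataFrame, metric_cols: list[str],
                     score_col: str = "bdi", subject_col: str = "id",
                     group_col: str = "group", session_col: str = "session",
                     mixed: bool = True) -> ModelResult:
    """Predict depression from group, time and mean-centred tract metrics.

    Group is coded 1 for controls (AUD reference, so the coefficient is
    negative when patients score higher); time 1 for the second session.
    Metric predictors are mean-centred.  The mixed variant adds a subject
    random intercept (REML) and falls back to OLS with a warning when the fit
    is singular or fails to converge.  VIFs are computed on the fixed design;
    predictors with VIF >= 10 are reported as multicollinearity flags.
    """
    sessions = sorted(table[session_col].unique())
    X = pd.DataFrame(index=table.index)
    X["group"] = (table[group_col] == "control").astype(float).to_numpy()
    X["time"] = (table[session_col] == sessions[-1]).astype(float).to_numpy()
    for c in metric_cols:
        v = table[c].to_numpy(float)
        X[c] = v - v.mean()
    y = table[score_col].to_numpy(float)
    vif = _vif(X)
    names = ["intercept"] + list(X.columns)
    warns: list[str] = []

    if mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = MixedLM(y, sm.add_constant(X).to_numpy(float),
                             groups=table[subject_col].to_numpy())
                fit = md.fit(reml=True)
            if np.all(np.isfinite(fit.bse_fe)):
                return ModelResult(
                    coefficients=_coef_frame(names, fit.fe_params,
                                             fit.bse_fe,
                                             fit.fe_params / fit.bse_fe,
                                             fit.pvalues[:len(names)]),
                    vif=vif,
                    random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
                    n_obs=int(fit.nobs), method="mixed", warnings=warns)
            warns.append("singular mixed fit; fell back to fixed effects")
        except (np.linalg.LinAlgError, ValueError) as exc:
            warns.append(f"mixed fit failed ({exc}); fell back to fixed effects")

    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return ModelResult(
        coefficients=_coef_frame(names, fit.params, fit.bse, fit.tvalues,
                                 fit.pvalues),
        vif=vif, n_obs=int(fit.nobs), method="ols", warnings=warns)


def consumption_regression(table: pd.DataFrame, value_col: str = "value",
                           units_col: str = "units_per_day",
                           subject_col: str = "id",
                           session_col: str = "session",
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-(tract, metric) regressions of metrics on alcohol consumption.

    For every tract x metric: simple OLS of the first-session value on
    units/day, and of the (second - first) session change on units/day.
    Returns a tidy frame with R, p (pre-adjustment) and Bonferroni flags
    across each target family.
    """
    sessions = sorted(table[session_col].unique())
    if len(sessions) < 2:
        raise ValueError("need two sessions for change scores")
    s1, s2 = sessions[0], sessions[-1]
    rows = []
    for (tract, metric), sub in table.groupby(["tract", "metric"]):
        wide = sub.pivot_table(index=subject_col, columns=session_col,
                               values=value_col)
        units = sub.groupby(subject_col)[units_col].first()
        for target, yv in (("E1", wide.get(s1)),
                           ("delta", None if s2 not in wide or s1 not in wide
                            else wide[s2] - wide[s1])):
            if yv is None:
                continue
            common = yv.dropna().index.intersection(units.dropna().index)
            if len(common) < 4:
                raise ValueError("need >= 4 subjects with consumption data")
            x = units.loc[common].to_numpy(float)
            if np.ptp(x) == 0:
                raise ValueError("constant consumption")
            res = sps.linregress(x, yv.loc[common].to_numpy(float))
            rows.append(dict(tract=tract, metric=metric, target=target,
                             R=float(res.rvalue), p=float(res.pvalue),
                             n=len(common)))
    out = pd.DataFrame(rows)
    out["significant"] = False
    for target, idx in out.groupby("target").groups.items():
        out.loc[idx, "significant"] = bonferroni_gate(
            out.loc[idx, "p"].to_numpy(), alpha=alpha)
    return out
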
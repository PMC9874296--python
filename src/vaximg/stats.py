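"""Temporal-endpoint summaries and the group-comparison models.

Endpoints measured repeatedly over post-vaccination timepoints are reduced
to two per-subject summaries — trapezoidal AUC and the value at the group
peak timepoint — and compared across treatment groups with:

* ANOVA on log-transformed summaries with Tukey studentized-range
  adjustment over all pairwise group contrasts;
* beta regression (logit link, common precision) for cell-type ratios,
  with ratios of exactly 0 shrunk to a 1e-5 pseudocount (and 1 to
  1 − 1e-5 symmetrically);
* ordinary linear models on square-root (proximity counts) or log
  (nearest-neighbour distances) transformed outcomes with unadjusted
  pairwise tests (comparisons prespecified);
* pairwise-complete Pearson correlation matrices between endpoint and
  cytokine panels.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, studentized_range, t as t_dist
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel

log = logging.getLogger(__name__)


@dataclass
class StatResult:
    """One fitted comparison: estimate on the model (transformed) scale."""

    comparison: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    transformation: str = "none"
    adjustment: str = "none"

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.ci_low > self.ci_high:
            raise ValueError("CI bounds out of order")


def results_frame(results: list[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Per-subject temporal summaries
# ---------------------------------------------------------------------------

def auc(timepoints, values) -> float:
    """Trapezoidal area under one subject's response curve.

    Integrates over the observed timepoints as-is: no baseline
    subtraction, no extrapolation beyond the first/last observation.
    Missing values must be removed by the caller (see :func:`auc_table`).
    """
    timepoints = np.asarray(timepoints, dtype=float)
    values = np.asarray(values, dtype=float)
    if timepoints.size != values.size:
        raise ValueError("timepoints and values differ in length")
    if timepoints.size < 2:
        raise ValueError("AUC needs at least 2 timepoints")
    if np.any(np.diff(timepoints) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    return float(np.trapezoid(values, timepoints))


def auc_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-subject AUC from a tidy endpoint table.

    Expects columns subject, group, cohort, time_hr, value (and optionally
    endpoint).  Missing values are dropped and the subject flagged
    ``complete=False``; series left with fewer than 2 points raise.
    """
    keys = [c for c in ("endpoint", "cohort", "group", "subject") if c in series.columns]
    rows = []
    for key, sub in series.groupby(keys, sort=True):
        sub = sub.sort_values("time_hr")
        n_total = len(sub)
        sub = sub.dropna(subset=["value"])
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["auc"] = auc(sub["time_hr"], sub["value"])
        rec["n_timepoints"] = len(sub)
        rec["complete"] = len(sub) == n_total
        if not rec["complete"]:
            log.warning("subject %s has missing timepoints; AUC over %d of %d points",
                        rec.get("subject"), len(sub), n_total)
        rows.append(rec)
    return pd.DataFrame(rows)


def group_max(series: pd.DataFrame) -> pd.DataFrame:
    """Each subject's value at the group's peak timepoint.

    The peak timepoint of a treatment group is the timepoint with the
    highest group-mean response; every subject of the group is then read
    at that shared timepoint, so the "maximum" summaries compare the peaks
    of the group-average curves.  Ties resolve to the earliest timepoint
    (logged).
    """
    keys = [c for c in ("endpoint", "cohort", "group") if c in series.columns]
    rows = []
    for key, sub in series.groupby(keys, sort=True):
        means = sub.groupby("time_hr")["value"].mean()
        peak = means.max()
        peak_times = means.index[means == peak]
        peak_time = float(peak_times.min())
        if len(peak_times) > 1:
            log.warning("tied group-mean peak at %s; using earliest %.3g hr",
                        list(peak_times), peak_time)
        at_peak = sub[sub["time_hr"] == peak_time]
        for _, r in at_peak.iterrows():
            rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            rec.update(subject=r["subject"], peak_time_hr=peak_time,
                       value=float(r["value"]))
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-comparison models
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _tukey_crit(alpha: float, k: int, df: float) -> float:
    # studentized_range.ppf is expensive; (alpha, k, df) recurs across calls
    return float(studentized_range.ppf(1 - alpha, k, df)) / np.sqrt(2.0)


def _pairwise_from_fit(params, cov, df_resid, rows_by_group, *, tukey: bool,
                       transformation: str, alpha: float = 0.05):
    """All pairwise group contrasts from a fitted linear model.

    ``rows_by_group`` maps group → design row producing that group's
    adjusted mean.  With ``tukey`` the p-values and CIs use the
    studentized-range distribution over k groups; otherwise unadjusted t.
    """
    groups = list(rows_by_group)
    k = len(groups)
    results = []
    for ga, gb in itertools.combinations(groups, 2):
        c = rows_by_group[ga] - rows_by_group[gb]
        est = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
            crit = 0.0
        elif tukey:
            q = abs(est) / se * np.sqrt(2.0)
            p = float(studentized_range.sf(q, k, df_resid))
            crit = _tukey_crit(alpha, k, float(df_resid))
        else:
            tval = est / se
            p = float(2.0 * t_dist.sf(abs(tval), df_resid))
            crit = float(t_dist.ppf(1 - alpha / 2, df_resid))
        results.append(StatResult(
            comparison=f"{ga} - {gb}", estimate=est, se=se,
            ci_low=est - crit * se, ci_high=est + crit * se, p_value=p,
            transformation=transformation,
            adjustment="tukey" if tukey else "none",
        ))
    return results


def _design(groups, cohorts=None, interaction=False):
    """Treatment-coded design matrix and per-group marginal-mean rows."""
    groups = pd.Series(groups, dtype="object")
    g_levels = sorted(groups.unique())
    cols = [np.ones(len(groups))]
    names = ["Intercept"]
    for g in g_levels[1:]:
        cols.append((groups == g).to_numpy(float))
        names.append(f"group[{g}]")
    c_levels = []
    if cohorts is not None:
        cohorts = pd.Series(cohorts, dtype="object")
        c_levels = sorted(cohorts.unique())
        for c in c_levels[1:]:
            cols.append((cohorts == c).to_numpy(float))
            names.append(f"cohort[{c}]")
        if interaction:
            for g in g_levels[1:]:
                for c in c_levels[1:]:
                    cols.append(((groups == g) & (cohorts == c)).to_numpy(float))
                    names.append(f"group[{g}]:cohort[{c}]")
    X = np.column_stack(cols)

    # Marginal-mean rows: average the design over cohort levels.
    rows_by_group = {}
    for g in g_levels:
        row = np.zeros(X.shape[1])
        row[0] = 1.0
        if g != g_levels[0]:
            row[names.index(f"group[{g}]")] = 1.0
        if c_levels:
            w = 1.0 / len(c_levels)
            for c in c_levels[1:]:
                row[names.index(f"cohort[{c}]")] = w
                if interaction and g != g_levels[0]:
                    row[names.index(f"group[{g}]:cohort[{c}]")] = w
        rows_by_group[g] = row
    return X, names, rows_by_group


def anova_log_tukey(
    values, groups, cohorts=None, interaction: bool = False
) -> list[StatResult]:
    """ANOVA on log-transformed summaries with Tukey-adjusted contrasts.

    Fits a linear model on log(values) with treatment (and optionally
    cohort and the treatment×cohort interaction) as factors, then reports
    every pairwise treatment contrast with studentized-range (Tukey)
    adjusted p-values and simultaneous CIs.  Estimates are log-scale mean
    differences, i.e. log fold-changes.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError(
            "log transform requires strictly positive values; decide on an "
            "offset policy before calling"
        )
    if len(set(groups)) < 2:
        raise ValueError("at least 2 groups are required")
    y = np.log(values)
    X, _, rows_by_group = _design(groups, cohorts, interaction)
    fit = sm.OLS(y, X).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    return _pairwise_from_fit(
        fit.params, fit.cov_params(), fit.df_resid, rows_by_group,
        tukey=True, transformation="log",
    )


def shrink_unit_interval(ratios, pseudo: float = 1e-5) -> np.ndarray:
    """Pull boundary ratios into (0, 1): 0 → pseudo, 1 → 1 − pseudo."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0) or np.any(ratios > 1):
        raise ValueError("ratios must lie in [0, 1]")
    out = ratios.copy()
    out[out == 0.0] = pseudo
    out[out == 1.0] = 1.0 - pseudo
    return out


@dataclass
class BetaRegressionFit:
    comparisons: list[StatResult]
    params: np.ndarray
    precision: float
    endog: np.ndarray
    converged: bool


def beta_regression(
    ratios, groups, pseudo: float = 1e-5
) -> BetaRegressionFit:
    """Beta regression of composition ratios on treatment (logit link).

    A single common precision φ is estimated; group effects act on the
    logit of the mean.  Pairwise Wald comparisons are unadjusted
    (prespecified contrasts).  Boundary ratios are shrunk by ``pseudo``
    first, so a ratio of exactly 0 enters the likelihood as ``pseudo``.
    """
    y = shrink_unit_interval(ratios, pseudo)
    X, _, rows_by_group = _design(groups)
    model = BetaModel(y, X)
    fit = model.fit(disp=False)
    if not fit.mle_retvals.get("converged", True):
        grad = model.score(fit.params)
        raise RuntimeError(
            f"beta regression did not converge; score vector {np.round(grad, 4)}"
        )
    # Last parameter is the precision; mean-submodel contrasts only.
    mean_params = fit.params[:-1]
    mean_cov = np.asarray(fit.cov_params())[:-1, :-1]
    comparisons = _pairwise_from_fit(
        mean_params, mean_cov, np.inf, rows_by_group,
        tukey=False, transformation="logit",
    )
    return BetaRegressionFit(
        comparisons=comparisons,
        params=np.asarray(fit.params),
        precision=float(np.exp(fit.params[-1]))
        if getattr(model, "link_precision", None) is not None
        else float(fit.params[-1]),
        endog=y,
        converged=True,
    )


def transformed_lm(
    outcome, groups, transform: str = "sqrt"
) -> list[StatResult]:
    """OLS on a sqrt- or log-transformed outcome with a treatment effect.

    Used for proximity counts (sqrt) and nearest-neighbour distances
    (log).  Pairwise group differences are reported with unadjusted
    t-tests, the comparisons being prespecified.
    """
    outcome = np.asarray(outcome, dtype=float)
    if transform == "sqrt":
        if np.any(outcome < 0):
            raise ValueError("sqrt transform requires non-negative outcomes")
        y = np.sqrt(outcome)
    elif transform == "log":
        if np.any(outcome <= 0):
            raise ValueError("log transform requires strictly positive outcomes")
        y = np.log(outcome)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    X, _, rows_by_group = _design(groups)
    fit = sm.OLS(y, X).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    return _pairwise_from_fit(
        fit.params, fit.cov_params(), fit.df_resid, rows_by_group,
        tukey=False, transformation=transform,
    )


def pearson_matrix(
    X: pd.DataFrame, Y: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every (X column, Y column) pair.

    Rows are paired samples; missing values are handled pairwise-complete.
    Pairs with fewer than ``min_n`` complete observations or a constant
    column get NaN (undefined, never silently 0).  Suitable for heatmap
    export (endpoints × cytokines).
    """
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of rows (samples)")
    r = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    p = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    for xc in X.columns:
        for yc in Y.columns:
            x = np.asarray(X[xc], dtype=float)
            y = np.asarray(Y[yc], dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_n or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                r.loc[xc, yc] = np.nan
                p.loc[xc, yc] = np.nan
                continue
            rr, pp = pearsonr(x[ok], y[ok])
            r.loc[xc, yc] = float(rr)
            p.loc[xc, yc] = float(pp)
    return r, p
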
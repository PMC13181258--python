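"""Allometric scaling fits and between-group slope/intercept tests.

Scaling relations are fit by ordinary least squares, either on raw axes or on
log10-log10 axes, in which case the slope is the scaling exponent b and the
fit is classified against an isometry reference (b = 1 for length-on-length
pairs) as hypoallometric (b < ref), isometric, or hyperallometric (b > ref).

Group differences in scaling use the classical nested-model F-tests: the
slope test compares a separate-slopes model against a common-slope model
(the group x predictor interaction); when slopes are homogeneous, the
intercept test compares a common-slope model with and without the group
offset (ANCOVA).
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import AllometryFit

ISOMETRY_REFERENCE = 1.0


def _as_xy(x, y, log_log: bool):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete (x, y) pairs")
    if log_log:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-log fit requires strictly positive x and y")
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; fit is singular")
    return x, y


def fit_scaling(
    x,
    y,
    log_log: bool = False,
    isometry_ref: float = ISOMETRY_REFERENCE,
    alpha: float = 0.05,
    response: str = "",
    predictor: str = "",
) -> AllometryFit:
    """OLS fit of y on x (log10 both axes when ``log_log``).

    Returns slope/intercept with standard errors, R², the overall F test of
    the slope (df = n - 2), and — for log-log fits — the allometry class from
    a two-sided t-test of the slope against ``isometry_ref`` at level
    ``alpha``.
    """
    xt, yt = _as_xy(x, y, log_log)
    n = len(xt)
    model = sm.OLS(yt, sm.add_constant(xt)).fit()
    slope = float(model.params[1])
    slope_se = float(model.bse[1])
    classification = "n/a"
    if log_log:
        if slope_se == 0:
            classification = "isometric" if slope == isometry_ref else (
                "hyperallometric" if slope > isometry_ref else "hypoallometric"
            )
        else:
            t_iso = (slope - isometry_ref) / slope_se
            p_iso = 2.0 * stats.t.sf(abs(t_iso), n - 2)
            if p_iso >= alpha:
                classification = "isometric"
            else:
                classification = "hyperallometric" if slope > isometry_ref else "hypoallometric"
    return AllometryFit(
        slope=slope,
        intercept=float(model.params[0]),
        slope_se=slope_se,
        intercept_se=float(model.bse[0]),
        r_squared=float(model.rsquared),
        F=float(model.fvalue),
        df=int(n - 2),
        p=float(model.f_pvalue),
        n=n,
        log_log=log_log,
        classification=classification,
        response=response,
        predictor=predictor,
    )


def _stack_groups(xA, yA, xB, yB, log_log: bool):
    xa, ya = _as_xy(xA, yA, log_log)
    xb, yb = _as_xy(xB, yB, log_log)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    grp = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    return x, y, grp


def compare_slopes(xA, yA, xB, yB, log_log: bool = False) -> tuple[float, int, float]:
    """Test whether two groups share a regression slope.

    F-test of the group x predictor interaction: separate-slopes model
    (x, group, x*group) against the common-slope reduction.  Returns
    (F, df_resid, p) with df_resid = n_total - 4.
    """
    x, y, grp = _stack_groups(xA, yA, xB, yB, log_log)
    X_full = np.column_stack([np.ones_like(x), x, grp, x * grp])
    X_red = X_full[:, :3]
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_resid = int(len(x) - 4)
    if full.ssr <= 0:  # both lines fit exactly
        F = 0.0 if np.isclose(red.ssr, full.ssr) else np.inf
    else:
        F = (red.ssr - full.ssr) / 1.0 / (full.ssr / df_resid)
    F = max(F, 0.0)  # guard tiny negative values from cancellation
    p = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
    return float(F), df_resid, p


def compare_intercepts(xA, yA, xB, yB, log_log: bool = False) -> tuple[float, int, float]:
    """Test for a group offset under a common slope (ANCOVA).

    F-test of the group main effect: common-slope model with a group offset
    against a single shared line.  Returns (F, df_resid, p) with
    df_resid = n_total - 3.  Meaningful when :func:`compare_slopes` does not
    reject slope homogeneity.
    """
    x, y, grp = _stack_groups(xA, yA, xB, yB, log_log)
    X_full = np.column_stack([np.ones_like(x), x, grp])
    X_red = X_full[:, :2]
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_resid = int(len(x) - 3)
    if full.ssr <= 0:
        F = 0.0 if np.isclose(red.ssr, full.ssr) else np.inf
    else:
        F = (red.ssr - full.ssr) / (full.ssr / df_resid)
    F = max(F, 0.0)  # guard tiny negative values from cancellation
    p = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
    return float(F), df_resid, p


def relative_investment(records: pd.DataFrame) -> dict:
    """Per-group fits of relative eye height (eye:head height) on head width.

    ``records`` needs columns ``group``, ``head_width_mm`` and either
    ``rel_eye_head`` or both ``eye_height_mm`` and ``head_height_mm``.
    Returns ``{"fits": {group: AllometryFit}, "slope_tests": {(gA, gB): (F, df, p)}}``.
    """
    df = records.copy()
    if "rel_eye_head" not in df.columns:
        df["rel_eye_head"] = df["eye_height_mm"] / df["head_height_mm"]
    fits = {}
    for group, sub in df.groupby("group", sort=False):
        if len(sub) >= 3:
            fits[group] = fit_scaling(
                sub["head_width_mm"], sub["rel_eye_head"], log_log=False,
                response="rel_eye_head", predictor="head_width_mm",
            )
    tests = {}
    groups = list(fits)
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = df[df["group"] == groups[i]]
            b = df[df["group"] == groups[j]]
            tests[(groups[i], groups[j])] = compare_slopes(
                a["head_width_mm"], a["rel_eye_head"],
                b["head_width_mm"], b["rel_eye_head"],
            )
    return {"fits": fits, "slope_tests": tests}
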
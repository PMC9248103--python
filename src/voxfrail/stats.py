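"""Association analysis between acoustic features and frailty.

Implements the statistical layer of the analysis: two-group one-way
ANOVA screens, univariate logistic regression with odds ratios on the
conventional reporting scales (A1 per 1-unit, A2 per 0.1, A3 per 10 Hz,
A4 per 0.1 change), Wald 95% confidence intervals, sex-stratified model
sets, odds-to-probability conversion, predicted-probability curves, and
a descriptive (robust/pre-frail vs frail) characteristics table.

The binary outcome everywhere is *frail* versus *robust or pre-frail*
combined.  Models are deliberately univariate and unadjusted; no
multiple-testing correction is applied to the decisions (a Bonferroni
column is emitted for reference only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "AssociationResult",
    "DescriptiveRow",
    "SCALE_UNITS",
    "anova_feature",
    "fit_logistic_or",
    "odds_to_probability",
    "probability_to_odds",
    "probability_curve",
    "stratified_associations",
    "descriptive_table",
    "anova_table",
]

#: Reporting-scale unit for each acoustic feature.
SCALE_UNITS: dict[str, float] = {"A1": 1.0, "A2": 0.1, "A3": 10.0, "A4": 0.1}

_FEATURES = ("A1", "A2", "A3", "A4")
_INDICES = ("CHS", "SOF", "FRAIL")


@dataclass
class AssociationResult:
    """One univariate logistic fit of frailty on a scaled feature."""

    feature: str
    index: str
    stratum: str  # all | male | female
    or_scaled: float
    ci95: tuple
    p_value: float
    scale_unit: float
    n: int
    converged: bool
    estimable: bool = True
    intercept: float = np.nan  # log-odds at feature = 0
    coef: float = np.nan  # log-odds slope per reporting unit

    def as_dict(self) -> dict:
        return {
            "feature": self.feature,
            "index": self.index,
            "stratum": self.stratum,
            "or": self.or_scaled,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_value": self.p_value,
            "scale_unit": self.scale_unit,
            "n": self.n,
            "converged": self.converged,
            "estimable": self.estimable,
            "intercept": self.intercept,
            "coef": self.coef,
        }


@dataclass
class DescriptiveRow:
    variable: str
    robust_prefrail: str
    frail: str
    p_value: float
    test_used: str


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_feature(values: Sequence[float], frail: Sequence[bool]) -> tuple[float, float]:
    """One-way ANOVA of a feature across frail vs robust/pre-frail.

    Returns (F, p).  Degenerate separation (zero within-group variance
    with different means) returns a large finite F and p = 0.
    """
    values = np.asarray(values, dtype=float)
    frail = np.asarray(frail, dtype=bool)
    keep = np.isfinite(values)
    values, frail = values[keep], frail[keep]
    g1, g0 = values[frail], values[~frail]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(g0) == 0 and np.var(g1) == 0:
        if np.mean(g0) == np.mean(g1):
            return 0.0, 1.0
        return 1e12, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sstats.f_oneway(g0, g1)
    if not np.isfinite(f):
        return 1e12, 0.0
    return float(f), float(p)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _firth_logit(x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Jeffreys-penalized (Firth) logistic fit for separated data.

    Returns (beta, cov) for design [1, x].
    """
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w
        u = X.T @ (y - p + h * (0.5 - p))
        step = cov @ u
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov


def fit_logistic_or(
    values: Sequence[float],
    frail: Sequence[bool],
    scale_unit: float = 1.0,
    feature: str = "",
    index: str = "",
    stratum: str = "all",
) -> AssociationResult:
    """Univariate maximum-likelihood logistic fit of frail ~ feature.

    The predictor is divided by ``scale_unit`` first, so the returned
    odds ratio is per one reporting unit (e.g. per 0.1 for A2/A4, per
    10 Hz for A3).  The 95% CI is Wald on the log-odds scale.  Perfect
    separation falls back to a Firth-penalized fit flagged
    ``converged=False``.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    values = np.asarray(values, dtype=float)
    frail = np.asarray(frail, dtype=bool)
    keep = np.isfinite(values)
    values, frail = values[keep], frail[keep]
    n = len(values)
    if n < 20:
        raise ValueError(f"need at least 20 observations, got {n}")
    if frail.all() or not frail.any():
        raise ValueError("both outcome classes must be present")
    if np.ptp(values) == 0:
        raise ValueError("no variation in predictor")

    x = values / scale_unit
    y = frail.astype(float)
    X = sm.add_constant(x)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        beta = res.params
        se = res.bse
        ok = (
            res.mle_retvals.get("converged", False)
            and np.all(np.isfinite(se))
            and np.max(np.abs(beta)) < 1e3
            and np.max(se) < 1e3
        )
        if not ok:
            raise PerfectSeparationError("unstable maximum-likelihood fit")
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        beta, cov = _firth_logit(x, y)
        se = np.sqrt(np.diag(cov))
        converged = False

    coef, coef_se = float(beta[1]), float(se[1])
    or_scaled = float(np.exp(coef))
    ci = (float(np.exp(coef - 1.96 * coef_se)), float(np.exp(coef + 1.96 * coef_se)))
    z = coef / coef_se if coef_se > 0 else np.inf
    p = float(2 * sstats.norm.sf(abs(z)))
    return AssociationResult(
        feature=feature, index=index, stratum=stratum,
        or_scaled=or_scaled, ci95=ci, p_value=p, scale_unit=scale_unit,
        n=n, converged=converged, intercept=float(beta[0]), coef=coef,
    )


def odds_to_probability(odds: float) -> float:
    """probability = odds / (1 + odds)."""
    if odds < 0:
        raise ValueError("odds must be non-negative")
    return odds / (1.0 + odds)


def probability_to_odds(p: float) -> float:
    """odds = p / (1 - p) for p in [0, 1)."""
    if not (0 <= p < 1):
        raise ValueError("probability must lie in [0, 1)")
    return p / (1.0 - p)


def probability_curve(model: AssociationResult, grid: Sequence[float]) -> np.ndarray:
    """Predicted probability of frailty along a raw-feature grid.

    Uses the fitted intercept and slope: p(x) = odds/(1+odds) with
    odds = exp(b0 + b1 * x/scale_unit).
    """
    if not model.converged:
        raise ValueError("model did not converge; probability curve unavailable")
    grid = np.asarray(grid, dtype=float)
    eta = model.intercept + model.coef * grid / model.scale_unit
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# batch associations
# ---------------------------------------------------------------------------

def _inestimable(feature, index, stratum, unit, n) -> AssociationResult:
    return AssociationResult(
        feature=feature, index=index, stratum=stratum,
        or_scaled=np.nan, ci95=(np.nan, np.nan), p_value=np.nan,
        scale_unit=unit, n=n, converged=False, estimable=False,
    )


def stratified_associations(
    features: pd.DataFrame,
    assessments: pd.DataFrame,
    strata: Sequence[str] = ("all", "male", "female"),
) -> pd.DataFrame:
    """Fit every feature x index x stratum univariate logistic model.

    ``features`` carries one row per participant (id, A1..A4);
    ``assessments`` one row per participant per index with the binary
    ``frail`` column and a ``sex`` column for stratification.  Returns a
    long table (4 features x 3 indices x len(strata) rows) with ORs on
    the reporting scales; strata lacking both outcome classes (or too
    small to fit) are marked inestimable.
    """
    out = []
    for index in _INDICES:
        sub = assessments[assessments["index"] == index][["id", "sex", "frail"]]
        merged = features.merge(sub, on="id", how="inner")
        merged = merged[merged["frail"].notna()]
        for stratum in strata:
            part = merged if stratum == "all" else merged[merged["sex"] == stratum]
            for feat in _FEATURES:
                unit = SCALE_UNITS[feat]
                vals = part[feat].to_numpy(dtype=float)
                frail = part["frail"].to_numpy(dtype=bool)
                fin = np.isfinite(vals)
                try:
                    res = fit_logistic_or(vals[fin], frail[fin], unit, feat, index, stratum)
                except ValueError:
                    res = _inestimable(feat, index, stratum, unit, int(fin.sum()))
                out.append(res.as_dict())
    df = pd.DataFrame(out)
    m = df["p_value"].notna()
    df["p_bonferroni"] = np.nan
    df.loc[m, "p_bonferroni"] = np.minimum(df.loc[m, "p_value"] * m.sum(), 1.0)
    return df


def anova_table(features: pd.DataFrame, assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-feature, per-index one-way ANOVA screen (frail vs not)."""
    rows = []
    for index in _INDICES:
        sub = assessments[assessments["index"] == index][["id", "frail"]]
        merged = features.merge(sub, on="id", how="inner")
        merged = merged[merged["frail"].notna()]
        for feat in _FEATURES:
            vals = merged[feat].to_numpy(dtype=float)
            frail = merged["frail"].to_numpy(dtype=bool)
            try:
                f, p = anova_feature(vals, frail)
            except ValueError:
                f, p = np.nan, np.nan
            rows.append({"index": index, "feature": feat, "F": f, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

def format_count_pct(count: int, total: int) -> str:
    """'43(87.8)' style cell: count with within-group percentage."""
    pct = 100.0 * count / total if total else np.nan
    return f"{count}({pct:.1f})"


def _mean_sd(v: np.ndarray) -> str:
    return f"{np.nanmean(v):.1f} ± {np.nanstd(v, ddof=1):.1f}"


def _cat_test(a_yes: int, a_no: int, b_yes: int, b_no: int) -> tuple[float, str]:
    table = np.array([[a_yes, a_no], [b_yes, b_no]])
    if table.sum() == 0 or table.sum(axis=1).min() == 0:
        return np.nan, "chi-square"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = sstats.fisher_exact(table)
        return float(p), "Fisher"
    chi2 = sstats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue), "chi-square"


#: (label, column, kind) rows of the descriptive table; categorical
#: entries map the column to a yes-flag via the given callable
_DESCRIPTIVE_SPEC = [
    ("Women", "sex", lambda s: s == "female"),
    ("Age (years)", "age_years", None),
    ("Body weight (kg)", "body_weight_kg", None),
    ("BMI (kg/m2)", "bmi", None),
    ("Weight loss", "weight_loss_pct_year", lambda s: s > 5.0),
    ("Exhaustion", "exhaustion_answer", lambda s: s.astype(str).str.lower() == "yes"),
    ("Slow gait speed", "gait_speed_m_s", lambda s: (s < 1.0) | s.isna()),
    ("Cannot complete 5 times CST", "chair_stand_able", lambda s: ~s.astype(bool)),
    ("ADL impairment", "adl_deterioration", lambda s: s.astype(str).str.lower() == "yes"),
    ("Polypharmacy", "drug_count", lambda s: s >= 8),
]


def descriptive_table(
    participants: pd.DataFrame,
    assessments: pd.DataFrame,
    index: str = "CHS",
) -> pd.DataFrame:
    """Characteristics of robust/pre-frail vs frail participants.

    Categorical rows show count(within-group %) compared by chi-square
    (Fisher's exact when any expected cell is below 5); continuous rows
    show mean ± SD compared by one-way ANOVA.
    """
    sub = assessments[assessments["index"] == index][["id", "frail"]]
    merged = participants.merge(sub, on="id", how="inner")
    merged = merged[merged["frail"].notna()]
    frail_mask = merged["frail"].astype(bool)
    g1 = merged[frail_mask]
    g0 = merged[~frail_mask]
    rows: list[DescriptiveRow] = []
    for label, col, flag in _DESCRIPTIVE_SPEC:
        if col not in merged.columns:
            continue
        if flag is None:
            v0 = g0[col].to_numpy(dtype=float)
            v1 = g1[col].to_numpy(dtype=float)
            try:
                _, p = anova_feature(
                    np.concatenate([v0, v1]),
                    np.concatenate([np.zeros(len(v0), bool), np.ones(len(v1), bool)]),
                )
                test = "ANOVA"
            except ValueError:
                p, test = np.nan, "ANOVA"
            rows.append(DescriptiveRow(label, _mean_sd(v0), _mean_sd(v1), p, test))
        else:
            y0 = int(flag(g0[col]).sum())
            y1 = int(flag(g1[col]).sum())
            p, test = _cat_test(y1, len(g1) - y1, y0, len(g0) - y0)
            rows.append(
                DescriptiveRow(
                    label,
                    format_count_pct(y0, len(g0)),
                    format_count_pct(y1, len(g1)),
                    p,
                    test,
                )
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.attrs["n_robust_prefrail"] = len(g0)
    df.attrs["n_frail"] = len(g1)
    return df
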
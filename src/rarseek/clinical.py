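"""Subtype classification, association testing and survival analysis.

Survival machinery: Kaplan-Meier and the log-rank test come from lifelines;
Cox proportional-hazards fits use statsmodels PHReg with Breslow tie
handling and Wald confidence intervals. The event is death within
``horizon_years`` of diagnosis (default 10); survivors and later deaths are
administratively censored at the horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("rarseek")

POSITIVE, NEGATIVE = "positive", "negative"


def classify_subtype(er: str, pr: str, her2: str) -> str:
    """IHC-based molecular subtype.

    Hormone-receptor positive (ER+ and/or PR+) splits on HER2 into Luminal A
    (HER2-) and Luminal B (HER2+); receptor-negative tumors are HER2 when
    HER2+ and TNBC when triple negative.
    """
    vals = {er, pr, her2}
    if not vals <= {POSITIVE, NEGATIVE}:
        raise ValueError(f"receptor status must be positive/negative, got {er, pr, her2}")
    hr_pos = er == POSITIVE or pr == POSITIVE
    if hr_pos:
        return "LuminalA" if her2 == NEGATIVE else "LuminalB"
    return "HER2" if her2 == POSITIVE else "TNBC"


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table (empty margin -> p=1)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table with an empty margin; p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def association_table(markers: pd.DataFrame, clinical_df: pd.DataFrame,
                      variables: dict[str, pd.Series]) -> pd.DataFrame:
    """Fisher tests of each marker against each binary clinical variable, with FDR."""
    rows = []
    for var_name, values in variables.items():
        levels = sorted(pd.Series(values).dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"{var_name}: expected 2 levels, got {levels}")
        for marker in markers.columns:
            table = [
                [int(((markers[marker] == 1) & (values == lv)).sum()) for lv in levels],
                [int(((markers[marker] == 0) & (values == lv)).sum()) for lv in levels],
            ]
            rows.append({"marker": marker, "variable": var_name,
                         "table": table, "p": fisher_exact_2x2(table)})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def apply_horizon(times, events, horizon_years: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Death within the horizon is the event; anything later is censored there."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    capped = np.minimum(t, horizon_years)
    ev = ((e == 1) & (t <= horizon_years)).astype(int)
    return capped, ev


@dataclass
class CoxRow:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float


@dataclass
class SurvivalResult:
    """Kaplan-Meier curves, log-rank test and Cox rows for one comparison."""

    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    logrank_statistic: float = float("nan")
    logrank_p: float = float("nan")
    cox: list[CoxRow] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def cox_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "covariate": r.covariate,
            "hazard_ratio": round(r.hazard_ratio, 4),
            "ci_low": round(r.ci_low, 4),
            "ci_high": round(r.ci_high, 4),
            "p": r.p,
        } for r in self.cox])


def km_estimate(times, events, group_labels=None) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival curve per group: DataFrame(time, survival).

    The curve starts at S(0)=1 and is the right-continuous product-limit
    step function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    groups = (np.asarray(["all"] * len(t), dtype=object)
              if group_labels is None else np.asarray(group_labels, dtype=object))
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask])
        sf = kmf.survival_function_
        out[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square statistic and p (k-1 df for k groups)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if len(pd.unique(g)) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def logrank_trend_test(times, events, ordinal_groups, scores=None) -> tuple[float, float]:
    """Log-rank test for trend across ordered groups (equally spaced scores).

    U = sum_g s_g (O_g - E_g); Var = s' V s with the hypergeometric
    covariance of event counts accumulated over risk sets; chi-square 1 df.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(ordinal_groups)
    levels = np.array(sorted(pd.unique(g)))
    if scores is None:
        scores = np.arange(len(levels), dtype=float)
    s = np.asarray(scores, dtype=float)
    O = np.zeros(len(levels))
    E = np.zeros(len(levels))
    V = np.zeros((len(levels), len(levels)))
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n = at_risk.sum()
        d = int(((t == tj) & (e == 1)).sum())
        ng = np.array([(at_risk & (g == lv)).sum() for lv in levels], dtype=float)
        dg = np.array([int(((t == tj) & (e == 1) & (g == lv)).sum()) for lv in levels])
        O += dg
        E += d * ng / n
        if n > 1:
            outer = np.outer(ng, ng) / n**2
            diag = np.diag(ng / n)
            V += d * (n - d) / (n - 1) * (diag - outer)
    U = float(s @ (O - E))
    var = float(s @ V @ s)
    if var <= 0:
        return 0.0, 1.0
    chi2 = U**2 / var
    return chi2, float(stats.chi2.sf(chi2, df=1))


def cox_fit(covariates: pd.DataFrame, times, events,
            horizon_years: float | None = 10.0) -> SurvivalResult:
    """Cox proportional-hazards fit (Breslow ties, Wald inference).

    ``covariates``: numeric DataFrame (binary covariates coded 0/1).
    Constant columns are excluded with a warning; non-convergence (e.g.
    monotone likelihood from perfect separation) raises naming the
    covariates.
    """
    X = covariates.astype(float)
    if horizon_years is not None:
        t, e = apply_horizon(times, events, horizon_years)
    else:
        t, e = np.asarray(times, dtype=float), np.asarray(events, dtype=int)
    result = SurvivalResult()
    keep = []
    for col in X.columns:
        if X[col].nunique() <= 1:
            msg = f"covariate {col!r} is constant; excluded from Cox model"
            warnings.warn(msg, stacklevel=2)
            result.notes.append(msg)
        else:
            keep.append(col)
    if not keep:
        raise ValueError("no non-constant covariates for Cox regression")
    X = X[keep]
    if e.sum() == 0:
        raise ValueError("no events within the horizon; Cox model undefined")
    model = PHReg(t, X.to_numpy(), status=e, ties="breslow")

    def _ok(fit):
        params = np.asarray(fit.params, dtype=float)
        se = np.asarray(fit.bse, dtype=float)
        return (np.all(np.isfinite(params)) and np.all(np.isfinite(se))
                and not np.any(se > 1e3))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=False)
        except np.linalg.LinAlgError:
            fit = None
        if fit is None or not _ok(fit):
            # near-monotone likelihood: Newton's Hessian goes singular or its
            # step overshoots; quasi-Newton still reaches the (finite) optimum
            # when one exists
            fit = model.fit(method="lbfgs", disp=False, maxiter=500)
            result.notes.append("Newton failed (near-separation); used L-BFGS")
    if not _ok(fit):
        raise RuntimeError(
            f"Cox fit did not converge (possible monotone likelihood) for covariates {keep}"
        )
    params = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    z = params / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    for i, col in enumerate(keep):
        hr = float(np.exp(params[i]))
        lo = float(np.exp(params[i] - 1.959963984540054 * se[i]))
        hi = float(np.exp(params[i] + 1.959963984540054 * se[i]))
        result.cox.append(CoxRow(covariate=str(col), hazard_ratio=hr, ci_low=lo,
                                 ci_high=hi, p=float(pvals[i]), coef=float(params[i]),
                                 se=float(se[i])))
    return result


def combined_marker(markers: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Logical AND of the named marker columns (1 iff simultaneously positive)."""
    missing = [n for n in names if n not in markers.columns]
    if missing:
        raise KeyError(f"unknown marker(s): {missing}")
    return markers[list(names)].all(axis=1).astype(int).to_numpy()


def three_level_groups(markers: pd.DataFrame, names: list[str]) -> np.ndarray:
    """{0 neither, 1 either, 2 both} carrier grouping for trend analysis."""
    if len(names) != 2:
        raise ValueError("three-level grouping is defined for exactly two markers")
    sub = markers[list(names)].to_numpy()
    return sub.sum(axis=1).astype(int)


def clinical_covariates(clinical_df: pd.DataFrame) -> pd.DataFrame:
    """0/1-coded age (>=50), stage (II vs I), ER, PR, HER2 design columns."""
    return pd.DataFrame({
        "age": (clinical_df["age_group"] == ">=50").astype(int),
        "stage": (clinical_df["stage"] != "I").astype(int),
        "er": (clinical_df["er"] == POSITIVE).astype(int),
        "pr": (clinical_df["pr"] == POSITIVE).astype(int),
        "her2": (clinical_df["her2"] == POSITIVE).astype(int),
    }, index=clinical_df.index)


def marker_survival(marker: np.ndarray, clinical_df: pd.DataFrame,
                    horizon_years: float = 10.0, adjust: bool = True,
                    marker_name: str = "marker") -> SurvivalResult:
    """KM + log-rank + (optionally covariate-adjusted) Cox for one binary marker."""
    t, e = apply_horizon(clinical_df["survival_years"], clinical_df["event"], horizon_years)
    groups = np.where(np.asarray(marker) == 1, "positive", "negative")
    result = SurvivalResult(km_curves=km_estimate(t, e, groups))
    if len(pd.unique(groups)) < 2:
        result.notes.append("single marker group; log-rank skipped")
        return result
    result.logrank_statistic, result.logrank_p = logrank_test(t, e, groups)
    X = clinical_covariates(clinical_df) if adjust else pd.DataFrame(index=clinical_df.index)
    X[marker_name] = np.asarray(marker, dtype=int)
    try:
        cox = cox_fit(X, clinical_df["survival_years"], clinical_df["event"], horizon_years)
        result.cox = cox.cox
        result.notes.extend(cox.notes)
    except (RuntimeError, ValueError) as exc:
        result.notes.append(f"Cox fit skipped: {exc}")
    return result
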
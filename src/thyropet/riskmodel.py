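"""Diagnostic performance and the combined radiomics + cytology risk model.

Operates on per-patient records carrying two dichotomous biomarkers — a
positive radiomics score (RS) and Bethesda class IV cytology — plus the
final histology.  Provides:

* 2x2 diagnostic performance (sensitivity/specificity/accuracy/NPV/PPV,
  odds ratio with Wald 95% CI);
* the 0/1/2 combined-biomarker score model (count of positive biomarkers)
  with per-group malignancy prevalence and odds ratios vs score 0;
* maximum-likelihood logistic regression (univariate/multivariate);
* association tests: Pearson chi-square, Fisher exact, Cochran-Armitage
  trend over the ordered score groups, Mann-Whitney U;
* Harrell's bootstrap optimism correction for the model AUC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .selection import rank_auc

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticPerformance",
    "diagnostic_performance",
    "combined_score",
    "combined_score_model",
    "logistic_fit",
    "association_tests",
    "bootstrap_optimism_auc",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ContingencyTable2x2:
    """Counts: a = test+/disease+, b = test+/disease-, c = test-/disease+,
    d = test-/disease-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_flags(cls, test: np.ndarray, disease: np.ndarray) -> "ContingencyTable2x2":
        test = np.asarray(test, dtype=bool)
        disease = np.asarray(disease, dtype=bool)
        return cls(
            int((test & disease).sum()),
            int((test & ~disease).sum()),
            int((~test & disease).sum()),
            int((~test & ~disease).sum()),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class DiagnosticPerformance:
    """Percent-scale test characteristics plus the Wald odds ratio."""

    sensitivity: float
    specificity: float
    accuracy: float
    npv: float
    ppv: float
    or_point: float
    or_ci_low: float
    or_ci_high: float
    continuity_corrected: bool = False


def odds_ratio_wald(
    t: ContingencyTable2x2,
) -> tuple[float, float, float, bool]:
    """Cross-product odds ratio with Wald 95% CI.

    The Haldane-Anscombe 0.5 continuity correction is applied to every
    cell only when at least one cell is zero, and the result is flagged;
    tables with all cells positive use the plain cross-product, so printed
    reference CIs reproduce exactly.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_point) - Z_95 * se)
    hi = math.exp(math.log(or_point) + Z_95 * se)
    return or_point, lo, hi, corrected


def diagnostic_performance(t: ContingencyTable2x2) -> DiagnosticPerformance:
    """Sens/spec/accuracy/NPV/PPV (percent) and the Wald OR of a 2x2 table."""

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return float("nan")
        return 100.0 * num / den

    or_point, lo, hi, corrected = odds_ratio_wald(t)
    return DiagnosticPerformance(
        sensitivity=ratio(t.a, t.a + t.c, "sensitivity"),
        specificity=ratio(t.d, t.b + t.d, "specificity"),
        accuracy=ratio(t.a + t.d, t.total, "accuracy"),
        npv=ratio(t.d, t.c + t.d, "NPV"),
        ppv=ratio(t.a, t.a + t.b, "PPV"),
        or_point=or_point,
        or_ci_low=lo,
        or_ci_high=hi,
        continuity_corrected=corrected,
    )


def combined_score(rs_positive: np.ndarray, bethesda_iv: np.ndarray) -> np.ndarray:
    """Number of positive biomarkers (0, 1 or 2) per patient."""
    return np.asarray(rs_positive, dtype=int) + np.asarray(bethesda_iv, dtype=int)


def combined_score_model(records: pd.DataFrame) -> dict:
    """Risk stratification by the 0/1/2 combined-biomarker score.

    Expects columns ``rs_positive``, ``bethesda_iv``, ``malignant``.
    Returns per-score malignant/total counts and prevalences, the odds
    ratio (with Wald CI) of malignancy for scores 1 and 2 each vs score 0,
    the model-level NPV (benign fraction at score 0) and PPV (malignant
    fraction at score 2), and the Cochran-Armitage trend p-value.
    """
    score = combined_score(records["rs_positive"], records["bethesda_iv"])
    malignant = records["malignant"].to_numpy(dtype=int)
    groups: dict[int, dict] = {}
    for s in (0, 1, 2):
        in_group = score == s
        n = int(in_group.sum())
        if n == 0:
            warnings.warn(f"score-{s} group empty: dropped", stacklevel=2)
            continue
        m = int(malignant[in_group].sum())
        groups[s] = {"n": n, "malignant": m, "prevalence_pct": 100.0 * m / n}
    if 0 not in groups or groups[0]["n"] == groups[0]["malignant"]:
        raise ValueError("score-0 group must be non-empty with >= 1 benign patient")

    m0, b0 = groups[0]["malignant"], groups[0]["n"] - groups[0]["malignant"]
    for s in (1, 2):
        if s not in groups:
            continue
        m, b = groups[s]["malignant"], groups[s]["n"] - groups[s]["malignant"]
        t = ContingencyTable2x2(m, b, m0, b0)
        or_point, lo, hi, corrected = odds_ratio_wald(t)
        groups[s].update(
            or_vs_score0=or_point, or_ci_low=lo, or_ci_high=hi,
            or_continuity_corrected=corrected,
        )

    counts = [
        (groups[s]["malignant"], groups[s]["n"]) for s in sorted(groups)
    ]
    trend_p = cochran_armitage_trend(
        [c[0] for c in counts], [c[1] for c in counts], scores=sorted(groups)
    )[1]
    out = {
        "groups": groups,
        "npv_score0_pct": 100.0 * (1 - groups[0]["malignant"] / groups[0]["n"]),
        "trend_p": trend_p,
    }
    if 2 in groups:
        out["ppv_score2_pct"] = groups[2]["prevalence_pct"]
    return out


def logistic_fit(
    records: pd.DataFrame,
    predictors: list[str],
    outcome: str = "malignant",
) -> pd.DataFrame:
    """Maximum-likelihood binary logistic regression (with intercept).

    Returns one row per predictor: OR = exp(coefficient), Wald 95% CI and
    p-value.  For a single binary predictor the OR equals the 2x2
    cross-product ratio exactly (saturated-model identity).  Raises on
    non-convergence or complete separation with actionable messages.
    """
    X = sm.add_constant(records[predictors].to_numpy(dtype=float))
    y = records[outcome].to_numpy(dtype=int)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
        raise ValueError(
            "complete separation: use an exact or penalized fallback"
        ) from err
    if not fit.mle_retvals.get("converged", True):
        raise ValueError(f"logistic fit did not converge: {fit.mle_retvals}")
    rows = []
    for k, name in enumerate(predictors, start=1):
        beta = fit.params[k]
        se = fit.bse[k]
        rows.append({
            "predictor": name,
            "or": math.exp(beta),
            "or_ci_low": math.exp(beta - Z_95 * se),
            "or_ci_high": math.exp(beta + Z_95 * se),
            "p": float(fit.pvalues[k]),
        })
    return pd.DataFrame(rows)


def stepwise_backward(
    records: pd.DataFrame,
    predictors: list[str],
    outcome: str = "malignant",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Backward elimination at Wald p < alpha, starting from the full model."""
    current = list(predictors)
    while len(current) > 1:
        fit = logistic_fit(records, current, outcome)
        worst = fit.loc[fit["p"].idxmax()]
        if worst["p"] <= alpha:
            break
        current.remove(worst["predictor"])
    return logistic_fit(records, current, outcome)


def cochran_armitage_trend(
    events: list[int], totals: list[int], scores: list[int] | None = None
) -> tuple[float, float]:
    """Cochran-Armitage test for trend in proportions over ordered groups.

    Returns (z statistic, two-sided p).  Scores default to 0, 1, 2, ...
    (the combined-biomarker score is ordinal by construction).
    """
    events = np.asarray(events, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if scores is None:
        scores = np.arange(len(events), dtype=float)
    s = np.asarray(scores, dtype=float)
    n = totals.sum()
    r = events.sum()
    if r == 0 or r == n:
        raise ValueError("degenerate margin: all or no events")
    pbar = r / n
    t_stat = float((s * (events - totals * pbar)).sum())
    var = pbar * (1 - pbar) * float((totals * s**2).sum() - (totals * s).sum() ** 2 / n)
    z = t_stat / math.sqrt(var)
    return z, 2.0 * stats.norm.sf(abs(z))


def association_tests(
    table: ContingencyTable2x2 | np.ndarray | None = None,
    score_groups: tuple[list[int], list[int]] | None = None,
    continuous: tuple[np.ndarray, np.ndarray] | None = None,
    yates: bool = False,
) -> dict:
    """The study's association-test battery; supply any subset of inputs.

    ``table``: a 2x2 table -> Pearson chi-square (no Yates correction by
    default) and two-sided Fisher exact.  ``score_groups``: (events,
    totals) per ordered group -> Cochran-Armitage trend.  ``continuous``:
    (values_group0, values_group1) -> Mann-Whitney U with tie correction.
    """
    out: dict = {}
    if table is not None:
        arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table, dtype=float)
        if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
            raise ValueError("degenerate margin in 2x2 table")
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
        out["chi_square"] = {"statistic": float(chi2), "p": float(p)}
        _, fisher_p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
        out["fisher_exact"] = {"p": float(fisher_p)}
    if score_groups is not None:
        z, p = cochran_armitage_trend(*score_groups)
        out["chi_square_trend"] = {"z": z, "p": p}
    if continuous is not None:
        u = stats.mannwhitneyu(*continuous, alternative="two-sided")
        out["mann_whitney"] = {"U": float(u.statistic), "p": float(u.pvalue)}
    return out


def bootstrap_optimism_auc(
    records: pd.DataFrame,
    predictors: list[str],
    outcome: str = "malignant",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Harrell's bootstrap optimism correction of the model AUC.

    Fit the logistic model on the full data (apparent AUC).  For each of
    ``n_boot`` resamples drawn with replacement: refit, compute the AUC on
    the resample and on the original data; optimism is the mean of the
    difference, and corrected AUC = apparent - optimism.  Resamples
    missing a class (or failing to fit) are redrawn; the count is
    reported.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    X = records[predictors].to_numpy(dtype=float)
    y = records[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")

    def fit_predict(Xf, yf, Xp):
        model = sm.Logit(yf, sm.add_constant(Xf, has_constant="add"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        return res.predict(sm.add_constant(Xp, has_constant="add"))

    apparent = rank_auc(fit_predict(X, y, X), y)
    optimisms = []
    redrawn = 0
    n = len(y)
    while len(optimisms) < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            redrawn += 1
            continue
        Xb = X[idx]
        try:
            auc_boot = rank_auc(fit_predict(Xb, yb, Xb), yb)
            auc_test = rank_auc(fit_predict(Xb, yb, X), y)
        except Exception:
            redrawn += 1
            continue
        optimisms.append(auc_boot - auc_test)
    optimism = float(np.mean(optimisms))
    return {
        "apparent_auc": float(apparent),
        "optimism": optimism,
        "corrected_auc": float(apparent - optimism),
        "n_boot": n_boot,
        "n_redrawn": redrawn,
    }
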
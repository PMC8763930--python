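"""Radiomics-signature construction: standardise, filter, select, score.

The stage order is fixed and matches the analysis it reproduces:

1. Z-score standardisation of every candidate feature (per acquiring
   centre by default, because scanners differ in calibration);
2. redundancy filtering: drop features strongly rank-correlated
   (|Spearman rho| > 0.7, BH-FDR-adjusted p < 0.05) with the anchor PET
   metrics SUVmax and MTV;
3. L1-penalised (LASSO) logistic regression with seeded, stratified
   ten-fold cross-validation to pick the informative features;
4. the radiomics score RS = sum_k beta_k * z_k (linear, no intercept);
5. a Youden-index cut-off on RS.

The reference signature this pipeline emulates selects shape_Sphericity
(coefficient -0.157) and glcm_Autocorrelation (coefficient -0.285) with an
RS cut-off of 0.049.  Orientation: both coefficients are negative and both
features are LOWER in malignant lesions, so malignant-like inputs yield a
HIGHER score — "RS-positive" (increased malignancy risk) is RS above the
cut-off.  :func:`youden_cutoff` establishes the side automatically from the
oriented AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureModel",
    "REFERENCE_SIGNATURE",
    "zscore_standardize",
    "redundancy_filter",
    "lasso_select",
    "radiomics_score",
    "rank_auc",
    "youden_cutoff",
    "build_signature",
]

#: Columns that are never treated as candidate features.
META_COLUMNS = ("patient_id", "center_id", "malignant", "bethesda_iv", "hurthle")

DEFAULT_ANCHORS = ("SUVmax", "MTV")


@dataclass
class SignatureModel:
    """A fitted radiomics signature: features, weights, RS cut-off."""

    selected_features: list[str]
    coefficients: dict[str, float]
    rs_cutoff: float = float("nan")
    #: side of the cut-off that is test-positive: "above" means RS > cutoff
    positive_direction: str = "above"
    auc: float = float("nan")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        return cls(**json.loads(Path(path).read_text()))


#: The published reference signature (for structural checks and examples;
#: its exact values are not recoverable from synthetic data).
REFERENCE_SIGNATURE = SignatureModel(
    selected_features=["shape_Sphericity", "glcm_Autocorrelation"],
    coefficients={"shape_Sphericity": -0.157, "glcm_Autocorrelation": -0.285},
    rs_cutoff=0.049,
    positive_direction="above",
)


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def zscore_standardize(table: pd.DataFrame, per_center: bool = True) -> pd.DataFrame:
    """Z-score every candidate feature: Z = (x - mean) / sd.

    With ``per_center=True`` (default) the mean and sample (n-1) SD are
    taken within each acquiring centre, removing additive and
    multiplicative scanner effects; otherwise pooled.  Raises on any
    zero-variance feature, naming it.
    """
    out = table.copy()
    features = _feature_columns(table)
    if per_center and "center_id" in table.columns:
        groups = [g for _, g in out.groupby("center_id", sort=False)]
    else:
        groups = [out]
    for g in groups:
        for col in features:
            sd = g[col].std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(
                    f"zero-variance feature {col!r} in standardization stratum"
                )
            out.loc[g.index, col] = (g[col] - g[col].mean()) / sd
    return out


def redundancy_filter(
    table: pd.DataFrame,
    anchors: tuple[str, ...] = DEFAULT_ANCHORS,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Remove features highly rank-correlated with the anchor PET metrics.

    A feature is removed iff, for at least one anchor, |Spearman rho|
    exceeds ``rho_threshold`` AND its Benjamini-Hochberg-adjusted p-value
    (one family across all feature-anchor tests) is below ``alpha``.
    Anchors themselves are never removed.  Constant features (undefined
    rho) are retained with a warning.  Returns (kept, removed, rho table);
    output is independent of column order.
    """
    for anchor in anchors:
        if anchor not in table.columns:
            raise ValueError(f"anchor {anchor!r} missing from table")
    candidates = sorted(set(_feature_columns(table)) - set(anchors))
    rows = []
    pvals, keys = [], []
    for col in candidates:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(
                f"constant feature {col!r}: Spearman rho undefined, retained",
                stacklevel=2,
            )
            rows.append({"feature": col, "anchor": None, "rho": np.nan, "p": np.nan})
            continue
        for anchor in anchors:
            rho, p = stats.spearmanr(x, table[anchor].to_numpy(dtype=float))
            rows.append({"feature": col, "anchor": anchor, "rho": rho, "p": p})
            pvals.append(p)
            keys.append((col, anchor))
    if pvals:
        rejected = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        rejected = np.zeros(0, dtype=bool)
    rho_table = pd.DataFrame(rows)
    adj = {key: rej for key, rej in zip(keys, rejected)}

    removed = set()
    for row in rows:
        if row["anchor"] is None:
            continue
        key = (row["feature"], row["anchor"])
        if abs(row["rho"]) > rho_threshold and adj[key]:
            removed.add(row["feature"])
    kept = [c for c in candidates if c not in removed]
    return kept, sorted(removed), rho_table


def lasso_select(
    table: pd.DataFrame,
    features: list[str] | None = None,
    outcome: str = "malignant",
    folds: int = 10,
    seed: int = 0,
    rule: str = "lambda-min",
    n_penalties: int = 30,
) -> SignatureModel:
    """LASSO logistic regression with seeded, stratified cross-validation.

    The L1 penalty is chosen on a logarithmic grid by ``folds``-fold
    stratified CV minimising the binomial deviance ("lambda-min"); the
    ``"1-se"`` rule (strongest penalty within one standard error of the
    best mean deviance) is available as an option.  Features must already
    be standardized.  Returns the nonzero-coefficient features and their
    coefficients; raises if nothing survives the chosen penalty.
    """
    if features is None:
        features = _feature_columns(table)
    X = table[features].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    n_events = min(int(y.sum()), int((1 - y).sum()))
    folds = min(folds, n_events)  # >= 1 event per fold
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Cs = np.logspace(-2.5, 1.5, n_penalties)
    model = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)

    if rule == "1-se":
        scores = model.scores_[1]  # folds x n_Cs, neg log-loss
        mean = scores.mean(axis=0)
        se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
        best = int(np.argmax(mean))
        ok = mean >= mean[best] - se[best]
        c_1se = float(Cs[np.argmax(ok)])  # smallest C (strongest penalty)
        model.set_params(Cs=[c_1se])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)

    coef = model.coef_.ravel()
    nonzero = np.flatnonzero(coef != 0.0)
    if nonzero.size == 0:
        raise ValueError(
            "no feature survives the selected penalty; rerun with rule="
            "'lambda-min' or fit an unpenalised model on pre-chosen features"
        )
    selected = [features[k] for k in nonzero]
    return SignatureModel(
        selected_features=selected,
        coefficients={features[k]: float(coef[k]) for k in nonzero},
    )


def radiomics_score(
    x: pd.DataFrame | dict[str, float], model: SignatureModel
) -> np.ndarray | float:
    """RS = sum_k coefficient_k * z_k over the signature features (no intercept)."""
    if isinstance(x, dict):
        missing = [f for f in model.selected_features if f not in x]
        if missing:
            raise ValueError(f"missing signature features: {missing}")
        return float(
            sum(model.coefficients[f] * x[f] for f in model.selected_features)
        )
    missing = [f for f in model.selected_features if f not in x.columns]
    if missing:
        raise ValueError(f"missing signature features: {missing}")
    values = x[model.selected_features].to_numpy(dtype=float)
    beta = np.array([model.coefficients[f] for f in model.selected_features])
    return values @ beta


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation, ties at 1/2.

    Probability that a random positive scores above a random negative;
    identical constant scores give exactly 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_cutoff(
    scores: np.ndarray,
    labels: np.ndarray,
    direction: str = "auto",
) -> tuple[float, float, float, float, str]:
    """Optimal dichotomisation cut-off by the Youden index.

    Scans all candidate thresholds (midpoints between adjacent distinct
    scores) and maximises J = sensitivity + specificity - 1; among ties
    the threshold maximising specificity wins (rule-in emphasis).

    ``direction`` fixes which side of the cut-off is test-positive:
    ``"above"``, ``"below"``, or ``"auto"`` (pick the side whose AUC
    exceeds 0.5, so that higher malignancy risk is "positive" whatever
    the score's sign convention).  Returns
    ``(cutoff, auc, sensitivity, specificity, direction)`` with AUC
    oriented along the chosen direction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.ptp(scores) == 0:
        raise ValueError("all scores identical: no cut-off exists")
    auc_above = rank_auc(scores, labels)
    if direction == "auto":
        direction = "above" if auc_above >= 0.5 else "below"
    if direction not in ("above", "below"):
        raise ValueError(f"unknown direction {direction!r}")
    auc = auc_above if direction == "above" else 1.0 - auc_above

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n1 = labels.sum()
    n0 = labels.size - n1
    best = None
    for c in candidates:
        positive = scores > c if direction == "above" else scores < c
        sens = (positive & (labels == 1)).sum() / n1
        spec = (~positive & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, float(c), float(sens), float(spec))
    _, cutoff, sens, spec = best
    return cutoff, float(auc), sens, spec, direction


def build_signature(
    table: pd.DataFrame,
    per_center: bool = True,
    anchors: tuple[str, ...] = DEFAULT_ANCHORS,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
    folds: int = 10,
    seed: int = 0,
    rule: str = "lambda-min",
) -> tuple[SignatureModel, pd.DataFrame]:
    """Full signature pipeline in the fixed stage order.

    standardize -> redundancy filter -> LASSO -> RS -> Youden cut-off.
    Returns the fitted :class:`SignatureModel` and the standardized table
    with an added ``RS`` column.
    """
    z = zscore_standardize(table, per_center=per_center)
    kept, _, _ = redundancy_filter(z, anchors, rho_threshold, alpha)
    model = lasso_select(z, features=kept, folds=folds, seed=seed, rule=rule)
    rs = radiomics_score(z, model)
    cutoff, auc, _, _, direction = youden_cutoff(
        rs, z["malignant"].to_numpy(dtype=int), direction="auto"
    )
    model.rs_cutoff = float(cutoff)
    model.positive_direction = direction
    model.auc = float(auc)
    z = z.copy()
    z["RS"] = rs
    z["rs_positive"] = (
        (rs > cutoff) if direction == "above" else (rs < cutoff)
    ).astype(int)
    return model, z
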
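"""Group comparison, feature selection and prognostic ROC evaluation.

The analysis tail mirrors a common biomarker workflow: per-feature
Mann-Whitney U screening at alpha (no multiplicity correction), L1
(LASSO) logistic selection tuned by stratified 10-fold cross-validation,
an unpenalized logistic combination of the selected markers, and ROC
evaluation (AUC with DeLong standard error and logit-scale 95% CI,
Youden-index operating point) of each marker and the combined score.

AUC is computed through the rank (Mann-Whitney) identity with ties
counted 1/2, so ``roc_analysis`` and ``mann_whitney_u`` agree by
construction: ``AUC = U / (n1 * n2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MWUResult",
    "LassoSelection",
    "LogisticModel",
    "ROCResult",
    "SeparationError",
    "mann_whitney_u",
    "screen_features",
    "lasso_select",
    "fit_logistic",
    "roc_analysis",
    "run_full_analysis",
    "cohort_summary",
    "permutation_auc_control",
]

EXACT_MWU_MAX_N = 16


class SeparationError(RuntimeError):
    """Raised when logistic ML estimation faces complete separation.

    Use a single-feature score instead, or opt into the penalized
    fallback by passing ``ridge_eps``.
    """


@dataclass(frozen=True)
class MWUResult:
    """Two-sided Mann-Whitney U comparison of one feature."""

    feature: str
    u: float
    p_value: float
    median_x: float
    median_y: float
    method: str  # "exact" | "asymptotic" | "degenerate"
    significant: bool = False


@dataclass(frozen=True)
class LassoSelection:
    """Outcome of CV-tuned L1 logistic feature selection."""

    lambda_path: np.ndarray
    chosen_lambda: float
    cv_deviance: np.ndarray  # mean held-out binomial deviance per lambda
    selected: list[str]
    candidates: list[str]
    coefficients: dict[str, float]  # at chosen lambda, standardized scale
    active_path: np.ndarray  # full-data active-set size at each lambda knot
    n_folds: int
    seed: int


@dataclass(frozen=True)
class LogisticModel:
    """Maximum-likelihood logistic combination of selected markers."""

    intercept: float
    coefficients: dict[str, float]
    scores: np.ndarray  # linear predictor per subject
    penalized: bool = False
    dropped_constant: tuple[str, ...] = ()

    def predict_score(self, table: pd.DataFrame) -> np.ndarray:
        score = np.full(len(table), self.intercept)
        for name, coef in self.coefficients.items():
            score = score + coef * table[name].to_numpy(dtype=float)
        return score


@dataclass(frozen=True)
class ROCResult:
    """AUC with DeLong uncertainty and the Youden operating point."""

    auc: float               # oriented so auc >= 0.5
    auc_raw: float           # before orientation (higher score = positive)
    se: float
    ci: tuple[float, float]
    cutoff: float            # threshold on the original score scale
    direction: str           # "higher" or "lower" score predicts positive
    sensitivity: float       # percent
    specificity: float       # percent
    fpr: np.ndarray
    tpr: np.ndarray
    n_positive: int
    n_negative: int


def mann_whitney_u(x, y, feature: str = "") -> MWUResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    The p-value is exact (full enumeration) when the pooled sample has
    at most 16 observations and no ties; otherwise the normal
    approximation with tie and continuity corrections is used.  A
    pooled sample with zero range (everything tied) reports U at its
    null mean and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return MWUResult(
            feature=feature, u=x.size * y.size / 2.0, p_value=1.0,
            median_x=float(np.median(x)), median_y=float(np.median(y)),
            method="degenerate",
        )

    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MWU_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MWUResult(
        feature=feature, u=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
        median_x=float(np.median(x)), median_y=float(np.median(y)), method=method,
    )


def screen_features(
    cohort: pd.DataFrame,
    features: list[str] | None = None,
    alpha: float = 0.05,
    outcome_col: str = "outcome",
) -> list[MWUResult]:
    """Mann-Whitney comparison of every feature between outcome groups.

    Features with two-sided p < alpha are flagged significant; no
    multiple-testing correction is applied.
    """
    if features is None:
        features = [c for c in cohort.columns if c.startswith(("rAPT_", "rASL_"))]
    y = cohort[outcome_col].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two outcome classes, found {classes}")
    g0 = cohort.loc[y == classes[0]]
    g1 = cohort.loc[y == classes[1]]
    results = []
    for name in features:
        res = mann_whitney_u(g0[name], g1[name], feature=name)
        flagged = res.p_value < alpha and res.method != "degenerate"
        results.append(
            MWUResult(
                feature=res.feature, u=res.u, p_value=res.p_value,
                median_x=res.median_x, median_y=res.median_y,
                method=res.method, significant=flagged,
            )
        )
    return results


def _binomial_deviance(y_true: np.ndarray, prob: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(-2.0 * np.mean(y_true * np.log(prob) + (1 - y_true) * np.log(1 - prob)))


def lasso_select(
    cohort: pd.DataFrame,
    candidates: list[str],
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 30,
    lambda_min_ratio: float = 1e-3,
    lambda_rule: str = "min",
    outcome_col: str = "outcome",
) -> LassoSelection:
    """Select markers by L1-penalized logistic regression with CV tuning.

    Candidates are standardized to zero mean / unit SD before
    penalization.  The penalty path is log-spaced from the smallest
    lambda that zeroes every coefficient down by ``lambda_min_ratio``;
    the chosen lambda minimizes mean held-out binomial deviance over
    stratified folds ("min" rule) or is the largest lambda within one
    standard error of that minimum ("1se").
    """
    if len(candidates) < 2:
        raise ValueError("LASSO selection needs at least 2 candidate features")
    if lambda_rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")
    y = cohort[outcome_col].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("outcome must be binary")
    y = (y == classes[1]).astype(int)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify {n_folds} folds: minority class has only "
            f"{counts.min()} subjects; reduce n_folds"
        )

    X = cohort[candidates].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    live = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - mu[live]) / sd[live]

    n = len(y)
    lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
    path = np.geomspace(lam_max * 1.000001, lam_max * lambda_min_ratio, n_lambdas)

    def _fit(Xtr, ytr, lam):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (len(ytr) * lam), solver="liblinear",
            max_iter=2000, tol=1e-8, random_state=0,
        )
        clf.fit(Xtr, ytr)
        return clf

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((n_folds, n_lambdas))
    for k, (tr, va) in enumerate(cv.split(Xs, y)):
        for j, lam in enumerate(path):
            clf = _fit(Xs[tr], y[tr], lam)
            fold_dev[k, j] = _binomial_deviance(y[va], clf.predict_proba(Xs[va])[:, 1])
    mean_dev = fold_dev.mean(axis=0)

    best = int(np.argmin(mean_dev))  # path descends, so first min = largest lambda
    if lambda_rule == "1se":
        se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        within = np.nonzero(mean_dev <= mean_dev[best] + se[best])[0]
        best = int(within[0])
    chosen = float(path[best])

    active_path = np.array(
        [int(np.count_nonzero(_fit(Xs, y, lam).coef_)) for lam in path]
    )
    final = _fit(Xs, y, chosen)
    coefs = dict(zip(candidates, final.coef_.ravel()))
    selected = [name for name, c in coefs.items() if c != 0.0]
    return LassoSelection(
        lambda_path=path, chosen_lambda=chosen, cv_deviance=mean_dev,
        selected=selected, candidates=list(candidates),
        coefficients=coefs, active_path=active_path, n_folds=n_folds, seed=seed,
    )


def _is_separated(scores: np.ndarray, y: np.ndarray) -> bool:
    """Complete separation: every positive score above every negative."""
    pos, neg = scores[y == 1], scores[y == 0]
    return bool(pos.min() > neg.max() or pos.max() < neg.min())


def fit_logistic(
    cohort: pd.DataFrame,
    features: list[str],
    outcome_col: str = "outcome",
    ridge_eps: float | None = None,
) -> LogisticModel:
    """Combine markers with an unpenalized logistic regression.

    The combined score of a subject is the fitted linear predictor.
    Zero-variance features are dropped (coefficient reported as 0).
    Complete separation raises :class:`SeparationError` unless
    ``ridge_eps`` opts into an L2-penalized fallback (penalty strength
    ``ridge_eps``), which is flagged on the returned model.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = cohort[outcome_col].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("outcome must be binary")
    y = (y == classes[1]).astype(int)

    X = cohort[list(features)].to_numpy(dtype=float)
    live = X.std(axis=0) > 0 if X.size else np.zeros(0, dtype=bool)
    dropped = tuple(f for f, ok in zip(features, live) if not ok)
    kept = [f for f, ok in zip(features, live) if ok]
    Xl = X[:, live]

    design = sm.add_constant(Xl, has_constant="add")
    try:
        with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.filterwarnings("error", message=".*[Ss]eparation.*")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
        scores = design @ params
        converged = bool(res.mle_retvals.get("converged", True))
        if not np.all(np.isfinite(params)) or (
            not converged and _is_separated(scores, y)
        ):
            raise PerfectSeparationError("complete separation detected")
    except (PerfectSeparationError, Warning, np.linalg.LinAlgError) as err:
        if ridge_eps is None:
            raise SeparationError(
                "complete separation in logistic fit; use a single-feature "
                "score or pass ridge_eps for a penalized fallback"
            ) from err
        clf = LogisticRegression(C=1.0 / ridge_eps, solver="lbfgs", max_iter=10000)
        if Xl.shape[1] == 0:
            Xl = np.zeros((len(y), 1))
            kept_fit: list[str] = []
        else:
            kept_fit = kept
        clf.fit(Xl, y)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()[: len(kept_fit)]])
        scores = params[0] + Xl[:, : len(kept_fit)] @ params[1:]
        coefs = dict(zip(kept_fit, params[1:]))
        coefs.update({f: 0.0 for f in dropped})
        return LogisticModel(
            intercept=float(params[0]), coefficients=coefs,
            scores=np.asarray(scores, dtype=float), penalized=True,
            dropped_constant=dropped,
        )

    coefs = dict(zip(kept, params[1:]))
    coefs.update({f: 0.0 for f in dropped})
    return LogisticModel(
        intercept=float(params[0]), coefficients=coefs,
        scores=np.asarray(scores, dtype=float), dropped_constant=dropped,
    )


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = sps.rankdata(combined)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


def roc_analysis(scores, outcomes, positive=1, cutoff_rule: str = "youden") -> ROCResult:
    """ROC evaluation of a score against a binary outcome.

    AUC uses the rank/pair-counting identity with ties counted 1/2;
    uncertainty is the DeLong estimator with a 95% CI computed on the
    logit scale (truncated to [0, 1]; degenerate when SE is 0).  The
    orientation is flipped if needed so AUC >= 0.5, with the direction
    recorded; the operating cutoff maximizes the Youden index
    (``cutoff_rule="youden"``) or minimizes the distance to the perfect
    corner (``"closest01"``).
    """
    if cutoff_rule not in ("youden", "closest01"):
        raise ValueError(f"unknown cutoff_rule {cutoff_rule!r}")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    pos_mask = y == positive
    n1, n0 = int(pos_mask.sum()), int((~pos_mask).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")

    auc_raw, _ = _delong_auc_variance(scores[pos_mask], scores[~pos_mask])
    if auc_raw < 0.5:
        direction = "lower"
        oriented = -scores
    else:
        direction = "higher"
        oriented = scores
    auc, var = _delong_auc_variance(oriented[pos_mask], oriented[~pos_mask])
    se = float(np.sqrt(var))

    if se > 0 and 0.0 < auc < 1.0:
        logit = np.log(auc / (1 - auc))
        half = 1.959963984540054 * se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - half)))
        hi = 1 / (1 + np.exp(-(logit + half)))
        ci = (float(max(lo, 0.0)), float(min(hi, 1.0)))
    else:
        ci = (auc, auc)

    fpr, tpr, thresholds = roc_curve(pos_mask.astype(int), oriented)
    if cutoff_rule == "youden":
        best = int(np.argmax(tpr - fpr))
    else:
        best = int(np.argmin(np.hypot(fpr, 1 - tpr)))
    cutoff = float(thresholds[best])
    if direction == "lower":
        cutoff = -cutoff
    return ROCResult(
        auc=auc, auc_raw=auc_raw, se=se, ci=ci, cutoff=cutoff,
        direction=direction, sensitivity=float(100 * tpr[best]),
        specificity=float(100 * (1 - fpr[best])), fpr=fpr, tpr=tpr,
        n_positive=n1, n_negative=n0,
    )


def run_full_analysis(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    n_folds: int = 10,
    seed: int = 0,
    lasso_on: str = "significant",
    features: list[str] | None = None,
    lambda_rule: str = "min",
    outcome_col: str = "outcome",
    ridge_eps: float | None = None,
) -> dict:
    """Screen, select, combine and evaluate — the full analysis tail.

    Returns a JSON-serializable report with the per-group feature
    summary (mean +/- SD and MWU p per feature), the screening and
    LASSO selection outcomes, the logistic combination, and an ROC
    table covering every selected marker plus the combined score.
    Deterministic given ``seed``.
    """
    if lasso_on not in ("significant", "all"):
        raise ValueError(f"lasso_on must be 'significant' or 'all', got {lasso_on!r}")
    if features is None:
        features = [c for c in cohort.columns if c.startswith(("rAPT_", "rASL_"))]
    y = cohort[outcome_col].to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("outcome must be binary")
    g0 = cohort.loc[y == classes[0]]
    g1 = cohort.loc[y == classes[1]]

    screening = screen_features(cohort, features, alpha=alpha, outcome_col=outcome_col)
    summary_rows = []
    for res in screening:
        summary_rows.append({
            "feature": res.feature,
            "mean_favorable": float(g0[res.feature].mean()),
            "sd_favorable": float(g0[res.feature].std(ddof=1)),
            "mean_unfavorable": float(g1[res.feature].mean()),
            "sd_unfavorable": float(g1[res.feature].std(ddof=1)),
            "u_statistic": res.u,
            "p_value": res.p_value,
            "significant": res.significant,
        })

    significant = [r.feature for r in screening if r.significant]
    candidates = significant if lasso_on == "significant" else list(features)

    lasso_report = None
    selection_note = ""
    if len(candidates) >= 2:
        sel = lasso_select(
            cohort, candidates, n_folds=n_folds, seed=seed,
            lambda_rule=lambda_rule, outcome_col=outcome_col,
        )
        selected = sel.selected
        if not selected:
            # penalty wiped every candidate: fall back to the strongest screen hit
            best = min(
                (r for r in screening if r.feature in candidates),
                key=lambda r: r.p_value,
            )
            selected = [best.feature]
            selection_note = "lasso selected no feature; fell back to smallest screening p"
        lasso_report = {
            "chosen_lambda": sel.chosen_lambda,
            "lambda_path": [float(v) for v in sel.lambda_path],
            "cv_deviance": [float(v) for v in sel.cv_deviance],
            "selected": selected,
            "candidates": sel.candidates,
        }
    elif len(candidates) == 1:
        selected = list(candidates)
        selection_note = "single candidate; lasso skipped"
    else:
        selected = []
        selection_note = "no significant feature; no model fitted"

    roc_rows = []
    model_report = None
    if selected:
        model = fit_logistic(cohort, selected, outcome_col=outcome_col, ridge_eps=ridge_eps)
        model_report = {
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "penalized": model.penalized,
        }
        pos = classes[1]
        for name in selected:
            roc = roc_analysis(cohort[name].to_numpy(dtype=float), y, positive=pos)
            roc_rows.append(_roc_row(name, roc))
        roc = roc_analysis(model.scores, y, positive=pos)
        roc_rows.append(_roc_row("combination", roc))

    return {
        "alpha": alpha,
        "seed": seed,
        "n_folds": n_folds,
        "lasso_on": lasso_on,
        "positive_class": str(classes[1]),
        "group_summary": summary_rows,
        "significant_features": significant,
        "lasso": lasso_report,
        "selected_features": selected,
        "selection_note": selection_note,
        "model": model_report,
        "roc_table": roc_rows,
    }


def _roc_row(name: str, roc: ROCResult) -> dict:
    return {
        "variable": name,
        "auc": roc.auc,
        "sensitivity_pct": roc.sensitivity,
        "specificity_pct": roc.specificity,
        "se": roc.se,
        "ci_low": roc.ci[0],
        "ci_high": roc.ci[1],
        "cutoff": roc.cutoff,
        "direction": roc.direction,
    }


DEFAULT_CATEGORICAL = ("sex", "hypertension", "diabetes", "hyperlipidemia", "gouty_arthropathy")
DEFAULT_CONTINUOUS = ("age", "nihss", "mrs_admission")


def cohort_summary(
    cohort: pd.DataFrame,
    categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
    outcome_col: str = "outcome",
) -> dict:
    """Demographic/comorbidity summary with group-difference p-values.

    Categorical variables get overall and per-group counts with
    percentages (two decimals) and a chi-square p-value (Fisher's exact
    for 2x2 tables with small expected counts); continuous variables
    get mean +/- SD and a Mann-Whitney p-value.  Requested covariates
    missing from the table are skipped with a warning.
    """
    y = cohort[outcome_col].to_numpy()
    classes = list(np.unique(y))
    n_total = len(cohort)
    variables: dict[str, dict] = {}

    for name in categorical:
        if name not in cohort.columns:
            warnings.warn(f"covariate {name!r} missing; omitted from summary")
            continue
        col = cohort[name]
        entry: dict = {"kind": "categorical"}
        levels = sorted(col.unique(), key=str)
        crosstab = pd.crosstab(col, cohort[outcome_col])
        if set(levels) <= {0, 1, True, False}:
            k = int(col.astype(bool).sum())
            entry["overall_count"] = k
            entry["overall_percent"] = round(100.0 * k / n_total, 2)
            for cls in classes:
                grp = col[y == cls].astype(bool)
                entry[f"count_{cls}"] = int(grp.sum())
                entry[f"percent_{cls}"] = round(100.0 * grp.sum() / len(grp), 2)
        else:
            entry["levels"] = {str(lv): int((col == lv).sum()) for lv in levels}
        entry["p_value"] = _categorical_p(crosstab.to_numpy())
        variables[name] = entry

    for name in continuous:
        if name not in cohort.columns:
            warnings.warn(f"covariate {name!r} missing; omitted from summary")
            continue
        col = cohort[name].to_numpy(dtype=float)
        entry = {
            "kind": "continuous",
            "overall_mean": float(np.mean(col)),
            "overall_sd": float(np.std(col, ddof=1)),
        }
        for cls in classes:
            grp = col[y == cls]
            entry[f"mean_{cls}"] = float(np.mean(grp))
            entry[f"sd_{cls}"] = float(np.std(grp, ddof=1)) if len(grp) > 1 else 0.0
        entry["p_value"] = mann_whitney_u(col[y == classes[0]], col[y == classes[1]]).p_value
        variables[name] = entry

    return {
        "n_total": n_total,
        "group_sizes": {str(cls): int((y == cls).sum()) for cls in classes},
        "variables": variables,
    }


def _categorical_p(table: np.ndarray) -> float:
    """Chi-square p, or Fisher's exact for sparse 2x2 tables."""
    table = np.asarray(table)
    if table.shape == (1, 2) or table.shape == (2, 1) or table.size == 0:
        return 1.0
    if table.shape == (2, 2):
        expected = sps.contingency.expected_freq(table)
        if (expected < 5).any():
            return float(sps.fisher_exact(table)[1])
    try:
        return float(sps.chi2_contingency(table)[1])
    except ValueError:
        return 1.0


def permutation_auc_control(
    cohort: pd.DataFrame,
    features: list[str],
    n_permutations: int = 200,
    seed: int = 0,
    outcome_col: str = "outcome",
    ridge_eps: float = 1e-6,
) -> np.ndarray:
    """Null control: refit the combination on permuted labels.

    For each permutation the logistic combination is refit on shuffled
    outcome labels and its score is evaluated (unoriented AUC) against
    the true labels.  A sound pipeline gives AUCs centred on 0.5 — the
    score learned from label noise carries no outcome information.
    """
    rng = np.random.default_rng(seed)
    y = cohort[outcome_col].to_numpy()
    classes = np.unique(y)
    aucs = np.empty(n_permutations)
    work = cohort[features].copy()
    for i in range(n_permutations):
        y_perm = rng.permutation(y)
        work[outcome_col] = y_perm
        model = fit_logistic(work, features, outcome_col=outcome_col, ridge_eps=ridge_eps)
        pos = y == classes[1]
        auc_raw, _ = _delong_auc_variance(model.scores[pos], model.scores[~pos])
        aucs[i] = auc_raw
    return aucs
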
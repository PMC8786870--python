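"""Model-improvement metrics for nested risk models.

AUC is computed in the Mann-Whitney formulation (ties count one half)
with DeLong variance for confidence intervals and the paired DeLong test
for comparing two models on the same subjects.  Reclassification metrics
follow the standard definitions: IDI is the between-model change in
discrimination slope; categorical NRI uses fixed risk categories
(default <5%, 5% to <25%, >=25%); the category-free NRI counts any
directional change in predicted risk.  Asymptotic normal inference
throughout, with a percentile bootstrap offered as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .models import MODEL_TERMS, ModelFit, ModelSpec, build_design, fit_glm, fit_model_suite

__all__ = [
    "ReclassReport",
    "CvReport",
    "roc_auc",
    "compare_auc",
    "idi",
    "categorical_nri",
    "category_free_nri",
    "bootstrap_reclass_ci",
    "evaluate_model_suite",
    "kfold_cv",
    "MODEL_COMPARISONS",
]

#: the five nested-model comparisons of the analysis (old, new)
MODEL_COMPARISONS: list[tuple[int, int]] = [(1, 2), (1, 3), (3, 4), (3, 5), (4, 5)]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class ReclassReport:
    """All improvement metrics for one (old model, new model) pair."""

    comparison: tuple[int, int]
    auc_old: float
    auc_old_ci: tuple[float, float]
    auc_new: float
    auc_new_ci: tuple[float, float]
    delta_auc: float
    delta_auc_p: float
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    cfnri: float
    cfnri_ci: tuple[float, float]
    cfnri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float
    risk_cuts: tuple[float, ...] = (0.05, 0.25)


@dataclass
class CvReport:
    k: int
    seed: int
    fold_auc: pd.DataFrame  # rows: fold, columns: model id
    mean_auc: pd.Series
    fold_metrics: pd.DataFrame  # per fold x comparison: nri/cfnri/idi
    mean_metrics: pd.DataFrame
    in_sample_auc: pd.Series | None = field(default=None)


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and the DeLong placement-value components V10 (cases) and
    V01 (controls) for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both a case and a control are required")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def roc_auc(
    scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series
) -> tuple[float, tuple[float, float]]:
    """AUC = P(score_case > score_control) + 0.5 P(tie), with a DeLong
    95% confidence interval (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - _Z975 * se), min(1.0, auc + _Z975 * se))
    return float(auc), ci


def compare_auc(
    scores_old: np.ndarray | pd.Series,
    scores_new: np.ndarray | pd.Series,
    labels: np.ndarray | pd.Series,
) -> dict[str, float]:
    """Paired DeLong test for the difference of two correlated AUCs."""
    old = np.asarray(scores_old, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if old.shape != new.shape or old.shape != labels.shape:
        raise ValueError("paired score vectors must cover identical subjects")
    a_old, v10_o, v01_o = _delong_components(old, labels)
    a_new, v10_n, v01_n = _delong_components(new, labels)
    m, n = len(v10_o), len(v01_o)
    s10 = np.cov(np.vstack([v10_o, v10_n])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_o, v01_n])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = a_new - a_old
    if var_delta <= 0:
        p = 1.0 if delta == 0 else 0.0
        z = np.inf if delta != 0 else 0.0
    else:
        z = delta / np.sqrt(var_delta)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return {"auc_old": float(a_old), "auc_new": float(a_new),
            "delta_auc": float(delta), "z": float(z), "p": p}


# ---------------------------------------------------------------------------
# reclassification metrics
# ---------------------------------------------------------------------------


def _check_probs(p_old: np.ndarray, p_new: np.ndarray) -> None:
    for name, p in (("p_old", p_old), ("p_new", p_new)):
        if np.any((p < 0) | (p > 1)):
            raise ValueError(f"{name} contains values outside [0, 1]")


def idi(
    labels: np.ndarray | pd.Series,
    p_old: np.ndarray | pd.Series,
    p_new: np.ndarray | pd.Series,
) -> tuple[float, tuple[float, float], float]:
    """Integrated discrimination improvement with asymptotic inference.

    IDI = (mean risk change among cases) - (mean risk change among
    controls); equivalently the change in discrimination slope.  The
    standard error combines the two within-group SEs of the paired risk
    differences.
    """
    labels = np.asarray(labels, dtype=int)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    _check_probs(p_old, p_new)
    diff = p_new - p_old
    d_case = diff[labels == 1]
    d_ctrl = diff[labels == 0]
    if len(d_case) < 2 or len(d_ctrl) < 2:
        raise ValueError("at least 2 cases and 2 controls required")
    est = float(d_case.mean() - d_ctrl.mean())
    se = float(
        np.sqrt(
            np.var(d_case, ddof=1) / len(d_case)
            + np.var(d_ctrl, ddof=1) / len(d_ctrl)
        )
    )
    if se == 0:
        return est, (est, est), (1.0 if est == 0 else 0.0)
    z = est / se
    return est, (est - _Z975 * se, est + _Z975 * se), float(2 * stats.norm.sf(abs(z)))


def _nri_from_moves(
    up: np.ndarray, down: np.ndarray, labels: np.ndarray
) -> tuple[float, tuple[float, float], float]:
    """Combine up/down movement indicators into the NRI estimate with
    Pencina-style asymptotic standard errors."""
    out = {}
    for grp, sign in ((1, 1.0), (0, -1.0)):
        sel = labels == grp
        n = int(sel.sum())
        pu, pd_ = up[sel].mean(), down[sel].mean()
        comp = sign * (pu - pd_)
        var = (pu + pd_ - (pu - pd_) ** 2) / n
        out[grp] = (comp, var)
    est = out[1][0] + out[0][0]
    var = out[1][1] + out[0][1]
    se = float(np.sqrt(var))
    if se == 0:
        return float(est), (float(est), float(est)), float("nan") if est == 0 else 0.0
    z = est / se
    return (
        float(est),
        (float(est - _Z975 * se), float(est + _Z975 * se)),
        float(2 * stats.norm.sf(abs(z))),
    )


def risk_category(p: np.ndarray, cuts: tuple[float, ...] = (0.05, 0.25)) -> np.ndarray:
    """Risk category index with left-closed, right-open intervals:
    [0, .05) low, [.05, .25) medium, [.25, 1] high by default."""
    return np.searchsorted(np.asarray(cuts), p, side="right")


def categorical_nri(
    labels: np.ndarray | pd.Series,
    p_old: np.ndarray | pd.Series,
    p_new: np.ndarray | pd.Series,
    cuts: tuple[float, ...] = (0.05, 0.25),
) -> tuple[float, tuple[float, float], float]:
    """Net reclassification improvement over fixed risk categories."""
    if list(cuts) != sorted(cuts) or any(not (0 < c < 1) for c in cuts):
        raise ValueError("cuts must be strictly increasing within (0, 1)")
    labels = np.asarray(labels, dtype=int)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    _check_probs(p_old, p_new)
    c_old = risk_category(p_old, cuts)
    c_new = risk_category(p_new, cuts)
    return _nri_from_moves((c_new > c_old).astype(float),
                           (c_new < c_old).astype(float), labels)


def category_free_nri(
    labels: np.ndarray | pd.Series,
    p_old: np.ndarray | pd.Series,
    p_new: np.ndarray | pd.Series,
) -> tuple[float, tuple[float, float], float]:
    """Category-free NRI: any increase/decrease of predicted risk counts."""
    labels = np.asarray(labels, dtype=int)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    _check_probs(p_old, p_new)
    return _nri_from_moves((p_new > p_old).astype(float),
                           (p_new < p_old).astype(float), labels)


def bootstrap_reclass_ci(
    labels: np.ndarray | pd.Series,
    p_old: np.ndarray | pd.Series,
    p_new: np.ndarray | pd.Series,
    statistic: str = "idi",
    n_boot: int = 1000,
    seed: int = 1,
    cuts: tuple[float, ...] = (0.05, 0.25),
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap confidence interval for a reclassification
    metric (``idi``, ``nri`` or ``cfnri``), offered as an alternative to
    the asymptotic intervals.  Resampling is stratified by case status
    so every replicate keeps both classes."""
    labels = np.asarray(labels, dtype=int)
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    fns = {
        "idi": lambda ell, o, nw: idi(ell, o, nw)[0],
        "nri": lambda ell, o, nw: categorical_nri(ell, o, nw, cuts)[0],
        "cfnri": lambda ell, o, nw: category_free_nri(ell, o, nw)[0],
    }
    if statistic not in fns:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = fns[statistic]
    est = fn(labels, p_old, p_new)
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.r_[rng.choice(case_idx, size=len(case_idx)),
                    rng.choice(ctrl_idx, size=len(ctrl_idx))]
        boots[b] = fn(labels[idx], p_old[idx], p_new[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(est), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# model-suite evaluation
# ---------------------------------------------------------------------------


def _reclass_report(
    comparison: tuple[int, int],
    labels: np.ndarray,
    p_old: np.ndarray,
    p_new: np.ndarray,
    cuts: tuple[float, ...],
) -> ReclassReport:
    auc_old, ci_old = roc_auc(p_old, labels)
    auc_new, ci_new = roc_auc(p_new, labels)
    cmp_ = compare_auc(p_old, p_new, labels)
    nri_est, nri_ci, nri_p = categorical_nri(labels, p_old, p_new, cuts)
    cf_est, cf_ci, cf_p = category_free_nri(labels, p_old, p_new)
    idi_est, idi_ci, idi_p = idi(labels, p_old, p_new)
    return ReclassReport(
        comparison=comparison,
        auc_old=auc_old, auc_old_ci=ci_old,
        auc_new=auc_new, auc_new_ci=ci_new,
        delta_auc=cmp_["delta_auc"], delta_auc_p=cmp_["p"],
        nri=nri_est, nri_ci=nri_ci, nri_p=nri_p,
        cfnri=cf_est, cfnri_ci=cf_ci, cfnri_p=cf_p,
        idi=idi_est, idi_ci=idi_ci, idi_p=idi_p,
        risk_cuts=cuts,
    )


def evaluate_model_suite(
    data: pd.DataFrame,
    cuts: tuple[float, ...] = (0.05, 0.25),
    comparisons: list[tuple[int, int]] | None = None,
) -> tuple[dict[int, ModelFit], list[ReclassReport]]:
    """Fit the five nested models in the whole sample and compare them.

    All models are fitted on the identical complete-case subject set
    (enforced); in-sample predicted probabilities feed the comparisons
    (1, 2), (1, 3), (3, 4), (3, 5) and (4, 5).
    """
    comparisons = comparisons or MODEL_COMPARISONS
    model_ids = tuple(sorted({m for pair in comparisons for m in pair}))
    fits = fit_model_suite(data, models=model_ids)
    index = None
    for m, fit in fits.items():
        if index is None:
            index = fit.fitted_prob.index
        elif not fit.fitted_prob.index.equals(index):
            raise ValueError(
                "models were fitted on differing subject sets; "
                "complete-case intersection violated"
            )
    labels = data.loc[index, "depression"].to_numpy(dtype=int)
    reports = [
        _reclass_report(
            (old, new),
            labels,
            fits[old].fitted_prob.to_numpy(),
            fits[new].fitted_prob.to_numpy(),
            cuts,
        )
        for old, new in comparisons
    ]
    return fits, reports


def reports_to_table(reports: list[ReclassReport]) -> pd.DataFrame:
    """Improvement metrics in a comparisons-as-columns layout."""
    cols = {}
    for r in reports:
        key = f"M{r.comparison[0]}->M{r.comparison[1]}"
        cols[key] = {
            "AUC_old": r.auc_old, "AUC_new": r.auc_new,
            "dAUC_p": r.delta_auc_p,
            "NRI": r.nri, "NRI_p": r.nri_p,
            "cfNRI": r.cfnri, "cfNRI_p": r.cfnri_p,
            "IDI": r.idi, "IDI_p": r.idi_p,
        }
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def kfold_cv(
    data: pd.DataFrame,
    k: int = 5,
    seed: int = 1,
    cuts: tuple[float, ...] = (0.05, 0.25),
    models: tuple[int, ...] = (1, 2, 3, 4, 5),
    comparisons: list[tuple[int, int]] | None = None,
) -> CvReport:
    """Outcome-stratified k-fold cross-validation of the model suite.

    Each fold is held out once; models are fitted on the remaining k-1
    folds and evaluated on the held-out subjects.  Metrics are averaged
    over folds with unweighted means.
    """
    comparisons = comparisons or MODEL_COMPARISONS
    needed = {"depression"} | {
        t for m in models for t in MODEL_TERMS[m] if t != "grs:bmi"
    }
    sub = data.dropna(subset=[c for c in needed if c in data.columns])
    y = sub["depression"].to_numpy(dtype=int)
    n_cases = int(y.sum())
    if k > n_cases:
        raise ValueError(f"k={k} exceeds the number of cases ({n_cases})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc, fold_rows = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        train = sub.iloc[train_idx]
        test = sub.iloc[test_idx]
        probs = {}
        for m in models:
            fit = fit_glm(train, ModelSpec("depression", tuple(MODEL_TERMS[m])))
            X_test = build_design(test, fit.spec.terms)
            X_test = X_test.reindex(columns=fit.design_columns, fill_value=0.0)
            eta = X_test.to_numpy() @ fit.params["beta"].to_numpy()
            probs[m] = 1.0 / (1.0 + np.exp(-eta))
        y_test = test["depression"].to_numpy(dtype=int)
        fold_auc.append({m: roc_auc(probs[m], y_test)[0] for m in models})
        for old, new in comparisons:
            nri_est = categorical_nri(y_test, probs[old], probs[new], cuts)[0]
            cf_est = category_free_nri(y_test, probs[old], probs[new])[0]
            idi_est = idi(y_test, probs[old], probs[new])[0]
            fold_rows.append(
                {
                    "fold": fold,
                    "comparison": f"M{old}->M{new}",
                    "nri": nri_est,
                    "cfnri": cf_est,
                    "idi": idi_est,
                }
            )
    fold_auc_df = pd.DataFrame(fold_auc)
    fold_metrics = pd.DataFrame(fold_rows)
    mean_metrics = fold_metrics.groupby("comparison")[["nri", "cfnri", "idi"]].mean()
    return CvReport(
        k=k,
        seed=seed,
        fold_auc=fold_auc_df,
        mean_auc=fold_auc_df.mean(),
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
    )
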
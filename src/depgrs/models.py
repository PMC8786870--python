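"""Regression analyses: per-SNP scans, GRS models and effect sizes.

All case-control models are binary logistic regressions fitted by maximum
likelihood; SNPs enter additively as risk-allele counts (0/1/2).  The
nested model ladder used throughout the package is

* Model 1: sex + age + province
* Model 2: sex + age + province + BMI
* Model 3: sex + age + province + GRS
* Model 4: sex + age + province + GRS + BMI
* Model 5: sex + age + province + GRS + BMI + GRS x BMI

Province enters as unordered dummies with the first (lexicographically
sorted) site as reference.  Inference is Wald throughout: two-sided
p-values and 95% confidence intervals from estimate +/- 1.96 SE; odds
ratios are exponentiated coefficients.  Deviance explained is
D^2 = 1 - deviance / null deviance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpec",
    "ModelFit",
    "EffectSizeReport",
    "PowerParams",
    "MODEL_TERMS",
    "build_design",
    "fit_glm",
    "fit_model_suite",
    "univariate_snp_scan",
    "grs_quartile_contrasts",
    "interaction_model",
    "interaction_grid",
    "group_compare",
    "cohens_d_from_summary",
    "cramers_v",
    "bh_adjust",
    "logistic_power",
]

#: the five nested risk models (term lists in design-matrix order)
MODEL_TERMS: dict[int, list[str]] = {
    1: ["sex", "age", "province"],
    2: ["sex", "age", "province", "bmi"],
    3: ["sex", "age", "province", "grs"],
    4: ["sex", "age", "province", "grs", "bmi"],
    5: ["sex", "age", "province", "grs", "bmi", "grs:bmi"],
}

_Z975 = float(stats.norm.ppf(0.975))
_SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, ordered term list and family of one regression model."""

    outcome: str
    terms: tuple[str, ...]
    family: str = "logistic"  # or "linear"

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if "grs:bmi" in self.terms and not (
            "grs" in self.terms and "bmi" in self.terms
        ):
            raise ValueError("grs:bmi requires both marginal terms grs and bmi")


@dataclass
class ModelFit:
    """Coefficient table and fit summary of one fitted model."""

    spec: ModelSpec
    params: pd.DataFrame  # index term; columns beta, se, p, or_, ci_low, ci_high
    deviance: float
    null_deviance: float
    converged: bool
    separation: bool
    n_used: int
    fitted_prob: pd.Series | None = field(default=None, repr=False)
    design_columns: list[str] = field(default_factory=list, repr=False)

    @property
    def d_squared(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return float(1.0 - self.deviance / self.null_deviance)


@dataclass(frozen=True)
class EffectSizeReport:
    cohens_d: float | None
    cramers_v: float | None
    test_used: str
    p: float


@dataclass(frozen=True)
class PowerParams:
    or_per_unit: float
    predictor_sd: float
    prevalence: float
    n: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.or_per_unit <= 0:
            raise ValueError("or_per_unit must be > 0")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.n < 10:
            raise ValueError("n must be >= 10")


# ---------------------------------------------------------------------------
# design matrices and GLM fitting
# ---------------------------------------------------------------------------


def build_design(data: pd.DataFrame, terms: tuple[str, ...] | list[str]) -> pd.DataFrame:
    """Expand a term list into a design matrix with intercept.

    ``province`` becomes site dummies (first sorted level = reference);
    ``grs_quartile`` becomes Q2/Q3/Q4 dummies (Q1 reference);
    ``grs:bmi`` is the raw product of the two columns; any other term is
    taken as a numeric column of ``data`` (this covers SNP dosages).
    """
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for term in terms:
        if term == "province":
            levels = sorted(pd.unique(data["province"].astype(str)))
            for lev in levels[1:]:
                cols[f"province[{lev}]"] = (data["province"].astype(str) == lev).to_numpy(
                    dtype=float
                )
        elif term == "grs_quartile":
            for lev in ("Q2", "Q3", "Q4"):
                cols[f"quartile[{lev}]"] = (
                    data["quartile"].astype(str) == lev
                ).to_numpy(dtype=float)
        elif term == "grs:bmi":
            cols["grs:bmi"] = (data["grs"] * data["bmi"]).to_numpy(dtype=float)
        else:
            cols[term] = data[term].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def _wald_table(params: np.ndarray, bse: np.ndarray, names: list[str],
                logistic: bool) -> pd.DataFrame:
    z = np.divide(params, bse, out=np.zeros_like(params), where=bse > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    tbl = pd.DataFrame(
        {
            "beta": params,
            "se": bse,
            "p": p,
            "ci_low": params - _Z975 * bse,
            "ci_high": params + _Z975 * bse,
        },
        index=names,
    )
    if logistic:
        with np.errstate(over="ignore"):  # separated fits carry huge betas
            tbl["or_"] = np.exp(tbl["beta"])
            tbl["or_ci_low"] = np.exp(tbl["ci_low"])
            tbl["or_ci_high"] = np.exp(tbl["ci_high"])
    return tbl


def fit_glm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood fit of one model on complete cases.

    Non-convergence and separation (divergent coefficients or perfect
    in-sample prediction) are flagged on the returned fit rather than
    raised, so scans over many SNPs degrade gracefully.
    """
    needed = {spec.outcome}
    for t in spec.terms:
        if t == "grs:bmi":
            needed |= {"grs", "bmi"}
        elif t == "grs_quartile":
            needed.add("quartile")
        else:
            needed.add(t)
    sub = data.dropna(subset=[c for c in needed if c in data.columns])
    X = build_design(sub, spec.terms)
    y = sub[spec.outcome].to_numpy(dtype=float)

    logistic = spec.family == "logistic"
    if logistic and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError(f"outcome {spec.outcome!r} is not binary 0/1")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if logistic:
            model = sm.GLM(y, X, family=sm.families.Binomial())
            res = model.fit(maxiter=100, tol=1e-8)
            deviance = float(res.deviance)
            null_dev = float(res.null_deviance)
            mu = res.fittedvalues
            separation = bool(
                np.max(np.abs(res.params.to_numpy()[1:], )) > _SEPARATION_BETA
                if len(res.params) > 1
                else False
            ) or bool(np.all((mu > 0.5) == (y > 0.5)) and
                      np.all(np.minimum(mu, 1 - mu) < 1e-6))
            converged = bool(res.converged)
        else:
            model = sm.OLS(y, X)
            res = model.fit()
            rss = float(np.sum(res.resid**2))
            tss = float(np.sum((y - y.mean()) ** 2))
            deviance, null_dev = rss, tss
            separation = False
            converged = True
            mu = res.fittedvalues

    tbl = _wald_table(
        res.params.to_numpy(), res.bse.to_numpy(), list(X.columns), logistic
    )
    return ModelFit(
        spec=spec,
        params=tbl,
        deviance=deviance,
        null_deviance=null_dev,
        converged=converged,
        separation=separation,
        n_used=len(sub),
        fitted_prob=pd.Series(np.asarray(mu), index=sub.index),
        design_columns=list(X.columns),
    )


def fit_model_suite(
    data: pd.DataFrame, models: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> dict[int, ModelFit]:
    """Fit the requested nested risk models on the common complete-case set."""
    needed = {"depression"}
    for m in models:
        needed |= {t for t in MODEL_TERMS[m] if t != "grs:bmi"}
    sub = data.dropna(subset=[c for c in needed if c in data.columns])
    return {
        m: fit_glm(sub, ModelSpec("depression", tuple(MODEL_TERMS[m])))
        for m in models
    }


# ---------------------------------------------------------------------------
# per-SNP scans with FDR control
# ---------------------------------------------------------------------------


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform."""
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def univariate_snp_scan(
    genotypes: pd.DataFrame,
    pheno: pd.DataFrame,
    outcome: str = "depression",
    covariates: tuple[str, ...] | None = None,
    transform: str = "auto",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted additive model per SNP, with BH-adjusted p.

    Logistic regression for the binary outcome; linear regression for a
    continuous outcome (e.g. BMI), in which case residual normality is
    checked with Shapiro-Wilk and the outcome transformed (natural log or
    rank-based inverse normal per ``transform``) when the gate fails.
    Monomorphic SNPs are reported with ``skipped='monomorphic'``.
    """
    if covariates is None:
        covariates = (
            ("sex", "age", "province", "bmi")
            if outcome == "depression"
            else ("sex", "age", "province")
        )
    family = "logistic" if outcome == "depression" else "linear"
    data = pheno.copy()

    if family == "linear" and transform != "none":
        base = fit_glm(data, ModelSpec(outcome, tuple(covariates), "linear"))
        resid = data[outcome].loc[base.fitted_prob.index] - base.fitted_prob
        sw_p = stats.shapiro(resid.to_numpy()[:5000]).pvalue
        if sw_p < normality_alpha:
            if transform in ("log", "auto") and (data[outcome] > 0).all():
                data[outcome] = np.log(data[outcome])
            else:
                data[outcome] = _rank_inverse_normal(data[outcome].to_numpy())

    rows = []
    for snp in genotypes.columns:
        col = genotypes[snp]
        nonmiss = col.dropna()
        if nonmiss.nunique() < 2:
            rows.append({"snp_id": snp, "beta": np.nan, "se": np.nan, "p": np.nan,
                         "n": int(nonmiss.size), "skipped": "monomorphic"})
            continue
        d = data.copy()
        d[snp] = col
        fit = fit_glm(d, ModelSpec(outcome, tuple(covariates) + (snp,), family))
        row = fit.params.loc[snp]
        entry = {
            "snp_id": snp,
            "beta": float(row["beta"]),
            "se": float(row["se"]),
            "p": float(row["p"]),
            "n": fit.n_used,
            "skipped": "",
        }
        if family == "logistic":
            entry.update(
                or_=float(row["or_"]),
                or_ci_low=float(row["or_ci_low"]),
                or_ci_high=float(row["or_ci_high"]),
            )
        rows.append(entry)
    out = pd.DataFrame(rows)
    tested = out["skipped"] == ""
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# GRS models
# ---------------------------------------------------------------------------


def grs_quartile_contrasts(
    data: pd.DataFrame, covariates: tuple[str, ...] = ("sex", "age", "province")
) -> ModelFit:
    """Logistic model of case status on GRS quartile (Q1 reference).

    Returns the fit; the Q2/Q3/Q4 rows of ``params`` are the three
    odds-ratio contrasts against the bottom quartile.
    """
    counts = data["quartile"].astype(str).value_counts()
    empty = [q for q in ("Q1", "Q2", "Q3", "Q4") if counts.get(q, 0) == 0]
    if empty:
        raise ValueError(f"empty GRS quartile group(s): {empty}")
    spec = ModelSpec("depression", tuple(covariates) + ("grs_quartile",))
    return fit_glm(data, spec)


def interaction_model(
    data: pd.DataFrame, covariates: tuple[str, ...] = ("sex", "age", "province")
) -> ModelFit:
    """Model 5: marginal GRS and BMI terms plus their raw product."""
    spec = ModelSpec("depression", tuple(covariates) + ("grs", "bmi", "grs:bmi"))
    return fit_glm(data, spec)


def interaction_grid(
    fit: ModelFit,
    data: pd.DataFrame,
    bmi_sds: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    n_grs: int = 25,
) -> pd.DataFrame:
    """Predicted case probability over a GRS grid at BMI strata
    mean + k*SD, other covariates at reference (categoricals) / means
    (numerics).  Used for interaction-profile plots."""
    grs_grid = np.linspace(data["grs"].min(), data["grs"].max(), n_grs)
    bmi_mean, bmi_sd = float(data["bmi"].mean()), float(data["bmi"].std())
    beta = fit.params["beta"]
    rows = []
    for k in bmi_sds:
        bmi = bmi_mean + k * bmi_sd
        for g in grs_grid:
            eta = beta["const"]
            for col in fit.design_columns:
                if col == "const" or col.startswith("province["):
                    continue  # reference site: dummies at 0
                if col == "grs":
                    eta += beta[col] * g
                elif col == "bmi":
                    eta += beta[col] * bmi
                elif col == "grs:bmi":
                    eta += beta[col] * g * bmi
                else:
                    eta += beta[col] * float(data[col].mean())
            rows.append(
                {
                    "grs": g,
                    "bmi_stratum": f"{k:+.0f}SD" if k else "mean",
                    "bmi": bmi,
                    "predicted_probability": float(1.0 / (1.0 + np.exp(-eta))),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# descriptive comparisons and effect sizes
# ---------------------------------------------------------------------------


def cohens_d_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d from group means, SDs and sizes."""
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / s_pooled)


def cramers_v(table: np.ndarray) -> float:
    """Cramer's V of a contingency table (plain Pearson chi-squared)."""
    t = np.asarray(table, dtype=float)
    chi2 = stats.chi2_contingency(t, correction=False)[0]
    n = t.sum()
    k = min(t.shape) - 1
    return float(np.sqrt(chi2 / (n * k))) if k > 0 and n > 0 else 0.0


def group_compare(
    values=None,
    groups=None,
    contingency: np.ndarray | None = None,
    normality_alpha: float = 0.05,
) -> EffectSizeReport:
    """Two-group comparison with an automatically chosen test.

    Quantitative data: Shapiro-Wilk per group, then Student's t (equal
    variances per Levene), Welch's t, or Mann-Whitney U when normality
    fails; pooled-SD Cohen's d is always reported.  A contingency table
    uses Pearson's chi-squared with Cramer's V.
    """
    if contingency is not None:
        t = np.asarray(contingency, dtype=float)
        p = float(stats.chi2_contingency(t, correction=False)[1])
        return EffectSizeReport(None, cramers_v(t), "chi_squared", p)

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    d = cohens_d_from_summary(a.mean(), a.std(ddof=1), len(a),
                              b.mean(), b.std(ddof=1), len(b))
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return EffectSizeReport(0.0, None, "student_t", 1.0)
    normal = (
        stats.shapiro(a[:5000]).pvalue >= normality_alpha
        and stats.shapiro(b[:5000]).pvalue >= normality_alpha
    )
    if normal:
        equal_var = stats.levene(a, b).pvalue >= normality_alpha
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "student_t" if equal_var else "welch_t"
        return EffectSizeReport(d, None, test, float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return EffectSizeReport(d, None, "mann_whitney", float(res.pvalue))


# ---------------------------------------------------------------------------
# power approximation
# ---------------------------------------------------------------------------


def logistic_power(params: PowerParams) -> float:
    """Approximate power of the two-sided Wald test for a normally
    distributed continuous predictor in logistic regression.

    Hsieh-style approximation: with effect size expressed per SD of the
    predictor, beta* = ln(OR) * SD, the Wald statistic is approximately
    normal with mean sqrt(n * P(1-P)) * beta* under the alternative
    (P = event prevalence at the predictor mean), so

        power = Phi(lambda - z_{1-a/2}) + Phi(-lambda - z_{1-a/2}).

    At OR = 1 this returns exactly the two-sided size alpha.
    """
    beta_star = abs(np.log(params.or_per_unit)) * params.predictor_sd
    lam = np.sqrt(params.n * params.prevalence * (1.0 - params.prevalence)) * beta_star
    z = stats.norm.ppf(1.0 - params.alpha / 2.0)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))
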
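"""Synthetic case-control study generator.

Emulates the structure of a multicentre primary-care depression study:
~1650 adults recruited at 7 sites, ~6.3% depression cases, genotyped on a
small candidate panel (30-56 biallelic SNPs, MAF >= 0.05, in HWE), with
BMI, sex and age as covariates.  Outcomes are drawn from a logistic model
whose linear predictor contains per-allele SNP effects and, optionally, a
GRS x BMI product term, so that every downstream stage (QC, concordance
selection, unweighted GRS, nested risk models, reclassification metrics)
can be exercised and calibrated without any external data.

Genotypes are drawn under Hardy-Weinberg proportions at each SNP's minor
allele frequency.  Linkage-disequilibrium blocks are produced with a
Gaussian copula: latent equicorrelated normals are thresholded at the HWE
genotype quantiles, with the latent correlation calibrated numerically so
the *dosage* correlation hits the requested target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "SnpPanelSpec",
    "EffectModel",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_outcome",
    "make_annotation",
    "simulate_study",
]

#: cases / (cases + controls) of the study being emulated: 104 / 1650
DEFAULT_PREVALENCE = 104 / 1650
DEFAULT_N_SUBJECTS = 1650
DEFAULT_N_SITES = 7
DEFAULT_FEMALE_PROP = 0.62


# ---------------------------------------------------------------------------
# panel specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpPanelSpec:
    """Specification of a biallelic SNP panel.

    Parameters
    ----------
    n_snps
        Number of SNPs in the panel.
    maf
        Minor-allele frequency per SNP, each in ``(0, 0.5]``.
    ld_blocks
        Optional list of ``(block_size, target_r)`` pairs.  Blocks are
        laid out consecutively from the first SNP; ``target_r`` is the
        target pairwise *dosage* correlation within the block.
    missing_rate
        Proportion of genotype calls set to missing, in ``[0, 0.2]``.
    literature_direction
        Per-SNP literature effect direction for the minor (effect)
        allele: ``+1`` risk, ``-1`` protective.
    discordant_fraction
        Fraction of SNPs whose *simulated* effect sign contradicts
        ``literature_direction`` (used to exercise concordance-based
        selection; flagged SNPs are spread evenly across the panel).
    """

    n_snps: int
    maf: np.ndarray
    ld_blocks: list[tuple[int, float]] | None = None
    missing_rate: float = 0.0
    literature_direction: np.ndarray = field(default=None)  # type: ignore[assignment]
    discordant_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("panel must contain at least one SNP")
        maf = np.asarray(self.maf, dtype=float)
        if maf.shape != (self.n_snps,):
            raise ValueError(f"maf must have length n_snps={self.n_snps}")
        for j, p in enumerate(maf):
            if not np.isfinite(p) or not (0.0 < p <= 0.5):
                raise ValueError(f"MAF of SNP index {j} is {p!r}; must be in (0, 0.5]")
        object.__setattr__(self, "maf", maf)
        if not (0.0 <= self.missing_rate <= 0.2):
            raise ValueError("missing_rate must be in [0, 0.2]")
        if not (0.0 <= self.discordant_fraction <= 1.0):
            raise ValueError("discordant_fraction must be in [0, 1]")
        if self.ld_blocks is not None:
            sizes = [b[0] for b in self.ld_blocks]
            if any(s < 2 for s in sizes):
                raise ValueError("LD block sizes must be >= 2")
            if sum(sizes) > self.n_snps:
                raise ValueError("LD block sizes sum to more than n_snps")
            if any(not (0.0 <= r < 1.0) for _, r in self.ld_blocks):
                raise ValueError("LD block target correlations must be in [0, 1)")
        if self.literature_direction is None:
            object.__setattr__(
                self, "literature_direction", np.ones(self.n_snps, dtype=int)
            )
        else:
            ld = np.asarray(self.literature_direction, dtype=int)
            if ld.shape != (self.n_snps,):
                raise ValueError("literature_direction must have length n_snps")
            if not np.all(np.isin(ld, [-1, 1])):
                raise ValueError("literature_direction entries must be +1 or -1")
            object.__setattr__(self, "literature_direction", ld)

    @property
    def discordant_mask(self) -> np.ndarray:
        """Boolean mask of SNPs whose true effect contradicts the literature.

        Deterministic: ``round(discordant_fraction * n_snps)`` SNPs, spread
        evenly across the panel.
        """
        k = int(round(self.discordant_fraction * self.n_snps))
        mask = np.zeros(self.n_snps, dtype=bool)
        if k > 0:
            idx = np.unique(np.round(np.linspace(0, self.n_snps - 1, k)).astype(int))
            mask[idx] = True
        return mask

    @property
    def snp_ids(self) -> list[str]:
        return [f"rs{j + 1:05d}" for j in range(self.n_snps)]

    @classmethod
    def default(
        cls,
        n_snps: int = 30,
        missing_rate: float = 0.0,
        discordant_fraction: float = 0.0,
        ld_blocks: list[tuple[int, float]] | None = None,
    ) -> "SnpPanelSpec":
        """Deterministic panel with MAFs evenly spaced over [0.10, 0.45]
        and alternating literature directions (risk/protective)."""
        maf = np.linspace(0.10, 0.45, n_snps)
        direction = np.where(np.arange(n_snps) % 2 == 0, 1, -1)
        return cls(
            n_snps=n_snps,
            maf=maf,
            ld_blocks=ld_blocks,
            missing_rate=missing_rate,
            literature_direction=direction,
            discordant_fraction=discordant_fraction,
        )


# ---------------------------------------------------------------------------
# effect model (generative truth)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectModel:
    """Generative logistic model for case status.

    The linear predictor is built from *centred* predictors so that the
    intercept controls the case prevalence approximately independently of
    the panel size::

        eta = intercept
              + sum_j beta_snp[j] * (g*_j - mean(g*_j))
              + beta_bmi * (bmi - mean) + beta_sex * (sex - mean)
              + beta_age * (age - mean) + site effects (sum-to-zero)
              + gamma_interaction * (GRS - mean(GRS)) * (bmi - mean(bmi))

    where ``g*_j`` is the dosage oriented to the literature risk allele and
    ``GRS = sum_j g*_j`` over the whole panel.  ``beta_snp`` is expressed on
    this risk-oriented scale, so a *discordant* SNP simply carries a
    negative entry.  Because only centring distinguishes the generative
    coding from the analysis coding, the product-term coefficient of a
    raw-scale logistic refit equals ``gamma_interaction`` exactly.
    """

    intercept: float
    beta_snp: np.ndarray
    beta_bmi: float = 0.0
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_site: np.ndarray | None = None
    gamma_interaction: float = 0.0

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta_snp, dtype=float))
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta_snp must be finite")
        object.__setattr__(self, "beta_snp", beta)
        for name in ("intercept", "beta_bmi", "beta_sex", "beta_age", "gamma_interaction"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 < expit(self.intercept) < 1.0):
            raise ValueError("intercept implies prevalence outside (0, 1)")

    @classmethod
    def study_defaults(
        cls,
        panel: SnpPanelSpec,
        prevalence: float = DEFAULT_PREVALENCE,
        or_per_allele: float = 1.35,
        interaction_or: float = 1.14,
        n_sites: int = DEFAULT_N_SITES,
    ) -> "EffectModel":
        """Effect sizes emulating the study: per-allele GRS odds ratio
        ~1.35, GRS x BMI interaction odds ratio ~1.14 per product unit,
        modest sex/age effects, no marginal BMI effect, no site effects.

        Discordant SNPs (per ``panel.discordant_mask``) receive a
        sign-flipped per-allele effect.
        """
        beta = np.full(panel.n_snps, np.log(or_per_allele))
        beta[panel.discordant_mask] *= -1.0
        return cls(
            intercept=float(logit(prevalence)),
            beta_snp=beta,
            beta_bmi=0.0,
            beta_sex=np.log(1.3),
            beta_age=0.01,
            beta_site=np.zeros(n_sites),
            gamma_interaction=np.log(interaction_or),
        )


@dataclass
class SimulatedStudy:
    """One simulated dataset plus its generative truth."""

    genotypes: pd.DataFrame
    pheno: pd.DataFrame
    annotation: pd.DataFrame
    truth: EffectModel
    panel: SnpPanelSpec
    seed: int


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _hwe_thresholds(p: float) -> tuple[float, float]:
    """Cumulative genotype probabilities under HWE (dosage 0 then <=1)."""
    q = 1.0 - p
    return q * q, q * q + 2.0 * p * q


def _dosage_from_uniform(u: np.ndarray, p: float) -> np.ndarray:
    t0, t1 = _hwe_thresholds(p)
    return (u >= t0).astype(float) + (u >= t1)


def _dosage_corr_given_latent(rho: float, p1: float, p2: float) -> float:
    """Dosage correlation implied by latent Gaussian correlation ``rho``
    when each latent normal is thresholded at its HWE quantiles."""
    if rho >= 1.0:
        rho = 1.0 - 1e-12
    cuts1 = stats.norm.ppf(_hwe_thresholds(p1))
    cuts2 = stats.norm.ppf(_hwe_thresholds(p2))
    cov = [[1.0, rho], [rho, 1.0]]
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)
    # E[g1 g2] = sum over joint tail probabilities: g = 1{z>=c0} + 1{z>=c1}
    e_g1g2 = 0.0
    for c1 in cuts1:
        for c2 in cuts2:
            # P(z1 >= c1, z2 >= c2) via inclusion-exclusion on the CDF
            e_g1g2 += (
                1.0
                - stats.norm.cdf(c1)
                - stats.norm.cdf(c2)
                + mvn.cdf([c1, c2])
            )
    mu1, mu2 = 2.0 * p1, 2.0 * p2
    sd1 = np.sqrt(2.0 * p1 * (1.0 - p1))
    sd2 = np.sqrt(2.0 * p2 * (1.0 - p2))
    return (e_g1g2 - mu1 * mu2) / (sd1 * sd2)


def _calibrate_latent_rho(target_r: float, p1: float, p2: float) -> float:
    """Latent correlation whose thresholded-dosage correlation equals
    ``target_r`` (bisection; thresholding attenuates, so latent >= target)."""
    if target_r <= 0.0:
        return 0.0
    f = lambda rho: _dosage_corr_given_latent(rho, p1, p2) - target_r  # noqa: E731
    hi = 1.0 - 1e-9
    if f(hi) < 0:  # target unreachable; use maximal coupling
        return hi
    return float(optimize.brentq(f, target_r, hi, xtol=1e-4))


def simulate_genotypes(
    panel: SnpPanelSpec, n_subjects: int, seed: int
) -> pd.DataFrame:
    """Draw a subjects x SNPs dosage matrix under HWE with optional LD.

    Returns a DataFrame indexed by subject id with one float column per
    SNP; values are 0/1/2 with NaN for missing calls.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n_subjects, panel.n_snps))

    # LD blocks overwrite the leading columns with copula-coupled draws
    if panel.ld_blocks:
        start = 0
        for size, target_r in panel.ld_blocks:
            cols = slice(start, start + size)
            p_block = float(np.mean(panel.maf[cols]))
            rho = _calibrate_latent_rho(target_r, p_block, p_block)
            # equicorrelated latent normals via a shared factor
            shared = rng.standard_normal((n_subjects, 1))
            own = rng.standard_normal((n_subjects, size))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            u[:, cols] = stats.norm.cdf(z)
            start += size

    dosages = np.empty((n_subjects, panel.n_snps))
    for j in range(panel.n_snps):
        dosages[:, j] = _dosage_from_uniform(u[:, j], panel.maf[j])

    if panel.missing_rate > 0:
        miss = rng.uniform(size=dosages.shape) < panel.missing_rate
        dosages[miss] = np.nan

    subjects = [f"S{i + 1:05d}" for i in range(n_subjects)]
    out = pd.DataFrame(dosages, index=pd.Index(subjects, name="subject_id"),
                       columns=panel.snp_ids)
    return out


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def simulate_covariates(
    n_subjects: int,
    n_sites: int = DEFAULT_N_SITES,
    seed: int = 1,
    female_prop: float = DEFAULT_FEMALE_PROP,
    bmi_mean: float = 27.0,
    bmi_sd: float = 4.0,
    underweight_rate: float = 0.0,
) -> pd.DataFrame:
    """Draw sex, age, recruitment site and BMI for ``n_subjects`` adults.

    Sex is Bernoulli (1 = female, default 62% female), age is a truncated
    normal on [18, 75], site is uniform over ``n_sites`` labels, and BMI is
    normal(27, 4) truncated to values strictly above 18.5 (the analysis
    excludes underweight subjects).  Set ``underweight_rate > 0`` to give
    that fraction of subjects a BMI in [15, 18.5] so the exclusion filter
    has something to remove.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    sex = (rng.uniform(size=n_subjects) < female_prop).astype(int)
    a, b = (18.0 - 50.0) / 15.0, (75.0 - 50.0) / 15.0
    age = stats.truncnorm.rvs(a, b, loc=50.0, scale=15.0, size=n_subjects,
                              random_state=rng)
    site = rng.integers(0, n_sites, size=n_subjects)
    # guarantee every site label appears (small-n convenience)
    if n_subjects >= n_sites:
        site[:n_sites] = np.arange(n_sites)
        rng.shuffle(site)
    lo, hi = (18.5 - bmi_mean) / bmi_sd, np.inf
    bmi = stats.truncnorm.rvs(lo, hi, loc=bmi_mean, scale=bmi_sd,
                              size=n_subjects, random_state=rng)
    if underweight_rate > 0:
        under = rng.uniform(size=n_subjects) < underweight_rate
        bmi[under] = rng.uniform(15.0, 18.5, size=int(under.sum()))
    subjects = [f"S{i + 1:05d}" for i in range(n_subjects)]
    return pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "province": [f"site_{s + 1}" for s in site],
            "bmi": bmi,
        },
        index=pd.Index(subjects, name="subject_id"),
    )


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------


def _oriented_dosages(genotypes: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    """Dosages oriented to the literature risk allele (protective flipped)."""
    direction = annotation.loc[genotypes.columns, "literature_direction"].to_numpy()
    g = genotypes.to_numpy(dtype=float)
    return np.where(direction < 0, 2.0 - g, g)


def simulate_outcome(
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    truth: EffectModel,
    annotation: pd.DataFrame,
    seed: int,
    target_prevalence: float | None = None,
) -> pd.DataFrame:
    """Draw case/control labels from the generative logistic model.

    Returns the covariate table with a ``depression`` column appended.
    If ``target_prevalence`` is given, the intercept is re-calibrated on
    the realized sample so the mean event probability equals it exactly
    (the stored intercept is otherwise used as-is).
    """
    if not genotypes.index.equals(covariates.index):
        raise ValueError("genotype and covariate tables index different subjects")
    if len(truth.beta_snp) != genotypes.shape[1]:
        raise ValueError("beta_snp length does not match the genotype panel")

    g_star = _oriented_dosages(genotypes, annotation)
    col_mean = np.nanmean(g_star, axis=0)
    gc = g_star - col_mean
    gc = np.where(np.isnan(gc), 0.0, gc)  # missing contributes its mean

    eta = gc @ truth.beta_snp
    bmi_c = covariates["bmi"].to_numpy() - covariates["bmi"].mean()
    eta += truth.beta_bmi * bmi_c
    eta += truth.beta_sex * (covariates["sex"].to_numpy() - covariates["sex"].mean())
    eta += truth.beta_age * (covariates["age"].to_numpy() - covariates["age"].mean())
    if truth.beta_site is not None and np.any(truth.beta_site):
        site_codes = pd.Categorical(covariates["province"]).codes
        effects = np.asarray(truth.beta_site, dtype=float)
        effects = effects - effects.mean()
        eta += effects[site_codes]
    grs_c = gc.sum(axis=1)
    eta += truth.gamma_interaction * grs_c * bmi_c

    if target_prevalence is not None:
        c = float(
            optimize.brentq(
                lambda c0: expit(c0 + eta).mean() - target_prevalence, -30.0, 30.0
            )
        )
    else:
        c = truth.intercept
    prob = expit(c + eta)
    rng = np.random.default_rng(seed)
    y = (rng.uniform(size=len(prob)) < prob).astype(int)
    out = covariates.copy()
    out["depression"] = y
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

# allele pairs cycle through strand-unambiguous combinations only
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


def make_annotation(panel: SnpPanelSpec) -> pd.DataFrame:
    """One annotation row per SNP: alleles, literature direction, source.

    The effect allele is the minor allele.  ``true_discordant`` records
    which SNPs were simulated with an effect sign contradicting the
    literature (truth metadata, available for tests only).
    """
    mask = panel.discordant_mask
    rows = []
    for j, snp in enumerate(panel.snp_ids):
        eff, other = _ALLELE_PAIRS[j % 4]
        rows.append(
            {
                "snp_id": snp,
                "chr": str(1 + j % 22),
                "pos": 10_000 + 1_000 * j,
                "effect_allele": eff,
                "other_allele": other,
                "literature_direction": int(panel.literature_direction[j]),
                "source": "candidate" if j % 3 == 0 else "gwas",
                "true_discordant": bool(mask[j]),
            }
        )
    return pd.DataFrame(rows).set_index("snp_id", drop=False)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def simulate_study(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_snps: int = 30,
    seed: int = 1,
    prevalence: float = DEFAULT_PREVALENCE,
    or_per_allele: float = 1.35,
    interaction_or: float = 1.14,
    discordant_fraction: float = 0.0,
    missing_rate: float = 0.0,
    n_sites: int = DEFAULT_N_SITES,
    underweight_rate: float = 0.0,
    ld_blocks: list[tuple[int, float]] | None = None,
    truth: EffectModel | None = None,
) -> SimulatedStudy:
    """Simulate a complete case-control study under the default conditions
    (n=1650 subjects, ~6.3% cases, 7 sites, per-allele OR 1.35,
    interaction OR 1.14 per GRS x BMI product unit)."""
    panel = SnpPanelSpec.default(
        n_snps=n_snps,
        missing_rate=missing_rate,
        discordant_fraction=discordant_fraction,
        ld_blocks=ld_blocks,
    )
    if truth is None:
        truth = EffectModel.study_defaults(
            panel,
            prevalence=prevalence,
            or_per_allele=or_per_allele,
            interaction_or=interaction_or,
            n_sites=n_sites,
        )
    ss = np.random.SeedSequence(seed)
    s_geno, s_cov, s_out = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    geno = simulate_genotypes(panel, n_subjects, seed=s_geno)
    cov = simulate_covariates(
        n_subjects, n_sites=n_sites, seed=s_cov, underweight_rate=underweight_rate
    )
    anno = make_annotation(panel)
    pheno = simulate_outcome(
        geno, cov, truth, anno, seed=s_out, target_prevalence=prevalence
    )
    return SimulatedStudy(
        genotypes=geno, pheno=pheno, annotation=anno, truth=truth,
        panel=panel, seed=seed,
    )
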
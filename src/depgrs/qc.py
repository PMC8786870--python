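"""Marker- and subject-level genotype quality control.

Implements the QC chain applied before risk-score construction:

1. exclusion of underweight subjects (BMI <= 18.5);
2. SNP call rate (markers called in < 95% of subjects are removed);
3. minor allele frequency (MAF < 0.05 removed);
4. the exact Hardy-Weinberg test, applied in controls only;
5. greedy LD pruning of SNP pairs with pairwise dosage R^2 above 0.8.

Every dropped marker/subject carries a machine-readable reason code and
the stage-wise counts reconcile (input = retained + dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "QcConfig",
    "SnpQcRecord",
    "QcResult",
    "call_rate",
    "minor_allele_freq",
    "hwe_exact_test",
    "ld_r2",
    "run_qc",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds of the QC chain (defaults are the analysis values)."""

    call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_alpha: float = 0.05
    ld_r2_max: float = 0.8
    bmi_min_exclusive: float = 18.5
    #: drop SNPs failing HWE in controls (set False to flag only)
    hwe_exclude: bool = True

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "maf_min", "hwe_alpha", "ld_r2_max"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass
class SnpQcRecord:
    snp_id: str
    call_rate: float
    maf: float
    hwe_p_controls: float
    ld_pruned: bool = False
    passed: bool = True
    reasons: list[str] = field(default_factory=list)


@dataclass
class QcResult:
    """Filtered tables plus the full audit trail."""

    genotypes: pd.DataFrame
    pheno: pd.DataFrame
    snp_records: list[SnpQcRecord]
    subjects_dropped: list[str]
    counts: dict[str, int]

    def report(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "call_rate": r.call_rate,
                "maf": r.maf,
                "hwe_p_controls": r.hwe_p_controls,
                "ld_pruned": r.ld_pruned,
                "passed": r.passed,
                "reasons": ";".join(r.reasons),
            }
            for r in self.snp_records
        ]
        return pd.DataFrame(rows).set_index("snp_id")


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------


def call_rate(dosage: np.ndarray | pd.Series) -> float:
    """Fraction of non-missing genotype calls in a dosage column."""
    g = np.asarray(dosage, dtype=float)
    if g.size == 0:
        raise ValueError("empty dosage column")
    return float(1.0 - np.isnan(g).mean())


def minor_allele_freq(dosage: np.ndarray | pd.Series) -> float:
    """Frequency of the less common allele over non-missing dosages.

    A tie at 0.5 returns 0.5.
    """
    g = np.asarray(dosage, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("all genotypes missing; MAF undefined")
    p = g.sum() / (2.0 * g.size)
    return float(min(p, 1.0 - p))


def _hwe_log_probs(n_het_values: np.ndarray, n: int, n_minor: int) -> np.ndarray:
    """Log conditional probabilities of heterozygote counts given allele
    counts: P(h) ∝ n! / (n_AA! h! n_aa!) * 2^h with fixed allele totals."""
    n_major = 2 * n - n_minor
    h = n_het_values
    n_hom_minor = (n_minor - h) // 2
    n_hom_major = (n_major - h) // 2
    lp = (
        gammaln(n + 1)
        - gammaln(n_hom_minor + 1)
        - gammaln(h + 1)
        - gammaln(n_hom_major + 1)
        + h * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return lp


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton-style).

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration no more probable than the observed
    one.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)
    if n_minor == 0:
        return 1.0
    # admissible het counts share the parity of the minor-allele total
    h_values = np.arange(n_minor % 2, n_minor + 1, 2)
    lp = _hwe_log_probs(h_values, n, n_minor)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    # observed het count on the minor-allele scale
    obs = n_het
    p_obs = probs[np.searchsorted(h_values, obs)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def ld_r2(dosage_i: np.ndarray | pd.Series, dosage_j: np.ndarray | pd.Series) -> float:
    """Squared Pearson correlation of two dosage columns on the
    pairwise-complete subjects.  Returns NaN (with a warning) if either
    column is constant on that subset."""
    gi = np.asarray(dosage_i, dtype=float)
    gj = np.asarray(dosage_j, dtype=float)
    ok = ~(np.isnan(gi) | np.isnan(gj))
    gi, gj = gi[ok], gj[ok]
    if gi.size < 2:
        raise ValueError("fewer than 2 pairwise-complete subjects")
    if np.std(gi) == 0 or np.std(gj) == 0:
        warnings.warn("constant dosage column; R^2 undefined, pair not prunable",
                      stacklevel=2)
        return float("nan")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# full QC chain
# ---------------------------------------------------------------------------


def _genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    g = dosage[~np.isnan(dosage)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def run_qc(
    genotypes: pd.DataFrame,
    pheno: pd.DataFrame,
    config: QcConfig | None = None,
) -> QcResult:
    """Apply the full QC chain, in order: underweight exclusion, call
    rate, MAF, HWE in controls, greedy LD pruning.

    LD pruning scans surviving SNP pairs in column order; of a pair with
    R^2 above the threshold, the member with the lower call rate is
    dropped (tie: the later column).
    """
    config = config or QcConfig()
    if not genotypes.index.equals(pheno.index):
        raise ValueError("genotype and phenotype tables index different subjects")

    # (1) underweight subjects
    keep = pheno["bmi"] > config.bmi_min_exclusive
    subjects_dropped = list(pheno.index[~keep])
    geno = genotypes.loc[keep].copy()
    ph = pheno.loc[keep].copy()
    if geno.shape[0] == 0:
        raise ValueError(
            f"no subjects remain after the BMI filter "
            f"(dropped {len(subjects_dropped)} of {len(pheno)})"
        )

    controls = ph["depression"] == 0 if "depression" in ph.columns else pd.Series(
        True, index=ph.index
    )

    records: dict[str, SnpQcRecord] = {}
    for snp in geno.columns:
        col = geno[snp].to_numpy(dtype=float)
        cr = call_rate(col)
        nonmiss = col[~np.isnan(col)]
        maf = minor_allele_freq(col) if nonmiss.size else float("nan")
        ctrl = geno.loc[controls, snp].to_numpy(dtype=float)
        ctrl = ctrl[~np.isnan(ctrl)]
        if ctrl.size:
            hwe_p = hwe_exact_test(*_genotype_counts(ctrl))
        else:
            hwe_p = float("nan")
        rec = SnpQcRecord(snp_id=snp, call_rate=cr, maf=maf, hwe_p_controls=hwe_p)
        if cr < config.call_rate_min:
            rec.passed = False
            rec.reasons.append("call_rate")
        if not rec.reasons and maf < config.maf_min:
            rec.passed = False
            rec.reasons.append("maf")
        if (
            not rec.reasons
            and config.hwe_exclude
            and np.isfinite(hwe_p)
            and hwe_p < config.hwe_alpha
        ):
            rec.passed = False
            rec.reasons.append("hwe")
        elif np.isfinite(hwe_p) and hwe_p < config.hwe_alpha:
            rec.reasons.append("hwe_flag")
        records[snp] = rec

    surviving = [s for s in geno.columns if records[s].passed]

    # (5) greedy LD pruning over surviving SNPs, column order
    pruned: set[str] = set()
    for a_idx in range(len(surviving)):
        a = surviving[a_idx]
        if a in pruned:
            continue
        for b_idx in range(a_idx + 1, len(surviving)):
            b = surviving[b_idx]
            if b in pruned:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = ld_r2(geno[a], geno[b])
            if np.isfinite(r2) and r2 > config.ld_r2_max:
                cra, crb = records[a].call_rate, records[b].call_rate
                victim = b if crb <= cra else a
                records[victim].ld_pruned = True
                records[victim].passed = False
                records[victim].reasons.append("ld")
                pruned.add(victim)
                if victim == a:
                    break

    final = [s for s in geno.columns if records[s].passed]
    if not final:
        stage = {
            "call_rate": sum("call_rate" in r.reasons for r in records.values()),
            "maf": sum("maf" in r.reasons for r in records.values()),
            "hwe": sum("hwe" in r.reasons for r in records.values()),
            "ld": sum("ld" in r.reasons for r in records.values()),
        }
        raise ValueError(f"no SNPs survive QC; failures by stage: {stage}")

    counts = {
        "subjects_in": len(pheno),
        "subjects_out": len(ph),
        "subjects_dropped_bmi": len(subjects_dropped),
        "snps_in": genotypes.shape[1],
        "snps_out": len(final),
        "snps_dropped_call_rate": sum(
            "call_rate" in r.reasons for r in records.values()
        ),
        "snps_dropped_maf": sum("maf" in r.reasons for r in records.values()),
        "snps_dropped_hwe": sum("hwe" in r.reasons for r in records.values()),
        "snps_dropped_ld": sum("ld" in r.reasons for r in records.values()),
    }
    return QcResult(
        genotypes=geno[final],
        pheno=ph,
        snp_records=[records[s] for s in genotypes.columns],
        subjects_dropped=subjects_dropped,
        counts=counts,
    )
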
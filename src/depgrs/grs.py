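"""Unweighted genetic-risk-score construction.

The score is the plain count of risk alleles over a selected SNP panel:
no per-SNP weights.  Selection keeps the SNPs whose fitted per-SNP
association in the sample has the same sign as the direction reported in
the literature (significance is not required); protective-oriented SNPs
are flipped (dosage g -> 2 - g) before summing; subjects missing any
genotype among the selected SNPs are excluded (complete-case rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceRecord",
    "concordance_select",
    "orient_to_risk",
    "compute_grs",
    "assign_quartiles",
    "build_grs",
]

QUARTILE_LABELS = ["Q1", "Q2", "Q3", "Q4"]


@dataclass(frozen=True)
class ConcordanceRecord:
    snp_id: str
    fitted_beta: float
    fitted_p: float
    literature_direction: int
    concordant: bool


def concordance_select(
    univariate_results: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Compare each SNP's fitted effect sign with its literature direction.

    ``univariate_results`` needs columns ``snp_id``, ``beta`` and ``p``
    (one row per SNP, as produced by the per-SNP scan).  Returns one
    record per SNP with a ``concordant`` flag; the selected panel is the
    concordant subset.  An exactly zero fitted beta counts as discordant.
    """
    missing = set(univariate_results["snp_id"]) - set(annotation.index)
    if missing:
        raise KeyError(f"SNPs missing from annotation: {sorted(missing)}")
    rows = []
    for _, row in univariate_results.iterrows():
        direction = int(annotation.loc[row["snp_id"], "literature_direction"])
        beta = float(row["beta"])
        concordant = beta != 0.0 and np.sign(beta) == direction
        rows.append(
            {
                "snp_id": row["snp_id"],
                "fitted_beta": beta,
                "fitted_p": float(row["p"]),
                "literature_direction": direction,
                "concordant": concordant,
            }
        )
    return pd.DataFrame(rows).set_index("snp_id", drop=False)


def orient_to_risk(
    genotypes: pd.DataFrame,
    annotation: pd.DataFrame,
    selected_snps: list[str] | None = None,
) -> pd.DataFrame:
    """Flip protective-oriented SNPs so every column counts risk alleles.

    Input dosages count the effect (minor) allele; for SNPs whose minor
    allele is protective in the literature, g becomes 2 - g.  Missing
    stays missing.
    """
    snps = list(selected_snps) if selected_snps is not None else list(genotypes.columns)
    g = genotypes[snps].to_numpy(dtype=float)
    valid = np.isnan(g) | np.isin(g, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"dosage {g[tuple(bad)]!r} at subject row {bad[0]}, SNP {snps[bad[1]]} "
            "is outside {0, 1, 2, missing}"
        )
    direction = annotation.loc[snps, "literature_direction"].to_numpy()
    oriented = np.where(direction < 0, 2.0 - g, g)
    return pd.DataFrame(oriented, index=genotypes.index, columns=snps)


def compute_grs(
    risk_matrix: pd.DataFrame, selected_snps: list[str] | None = None
) -> tuple[pd.DataFrame, int]:
    """Sum risk-allele counts per subject over the selected SNPs.

    Subjects with any missing dosage among the selected SNPs are dropped
    (complete-case rule); the number removed is returned alongside.
    """
    snps = list(selected_snps) if selected_snps is not None else list(risk_matrix.columns)
    if not snps:
        raise ValueError("selected SNP set is empty")
    sub = risk_matrix[snps]
    complete = ~sub.isna().any(axis=1)
    n_dropped = int((~complete).sum())
    grs = sub.loc[complete].sum(axis=1).astype(int)
    out = pd.DataFrame({"grs": grs})
    out.index.name = "subject_id"
    return out, n_dropped


def assign_quartiles(grs_values: pd.Series | np.ndarray) -> pd.Series:
    """Label each subject Q1..Q4 by sample quartile of the GRS.

    Cut-points are the sample quartiles (linear interpolation); a value
    equal to a cut-point goes to the lower stratum, so Q1 is the
    reference low-risk group and Q4 the highest.
    """
    values = pd.Series(grs_values)
    if len(values) < 4:
        raise ValueError("at least 4 subjects are required for quartiles")
    if values.nunique() < 4:
        warnings.warn(
            "fewer than 4 distinct GRS values; quartile contrasts may be degenerate",
            stacklevel=2,
        )
    q1, q2, q3 = np.quantile(values.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    labels = np.select(
        [values <= q1, values <= q2, values <= q3],
        ["Q1", "Q2", "Q3"],
        default="Q4",
    )
    return pd.Series(
        pd.Categorical(labels, categories=QUARTILE_LABELS, ordered=True),
        index=values.index,
        name="quartile",
    )


def build_grs(
    genotypes: pd.DataFrame,
    annotation: pd.DataFrame,
    univariate_results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Full chain: concordance selection -> orientation -> unweighted sum
    -> quartiles.

    Returns ``(grs_table, selection_report, n_subjects_dropped)`` where
    ``grs_table`` has columns ``grs`` and ``quartile`` indexed by subject.
    """
    report = concordance_select(univariate_results, annotation)
    selected = list(report.index[report["concordant"]])
    if not selected:
        raise ValueError("no concordant SNPs; cannot build a risk score")
    oriented = orient_to_risk(genotypes, annotation, selected)
    grs_table, n_dropped = compute_grs(oriented, selected)
    grs_table["quartile"] = assign_quartiles(grs_table["grs"])
    grs_table.attrs["snp_set"] = selected
    return grs_table, report, n_dropped
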
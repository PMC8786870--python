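"""Readers and writers for the pipeline's table dialects.

* genotype TSV: rows = subjects, columns = SNP ids, cells 0/1/2/NA;
* phenotype CSV: subject_id, depression (0/1), bmi, sex (0/1), age, province;
* annotation CSV: snp_id, chr, pos, effect_allele, other_allele,
  literature_direction (+1/-1), source;
* minimal VCF (optional): biallelic sites, GT field only; dosage is the
  count of the annotation's effect allele.

Every file written here starts with comment lines recording the package
version, the seed and a configuration hash, so outputs are traceable;
readers skip ``#`` lines.  Coordinates (chr, pos, 1-based) are carried as
opaque metadata and never used in computation.  Alleles are compared as
given (no strand flipping); ambiguous A/T and C/G SNPs load with a
warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "header_lines",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_pheno_csv",
    "read_pheno",
    "write_annotation_csv",
    "read_annotation",
    "read_vcf",
    "write_vcf",
]

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


def header_lines(seed: int | None = None, config_hash: str | None = None) -> str:
    parts = [f"# depgrs {__version__}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if config_hash is not None:
        parts.append(f"# config_hash={config_hash}")
    return "\n".join(parts) + "\n"


def _write_table(df: pd.DataFrame, path: Path, sep: str, seed, config_hash,
                 na_rep: str = "NA", index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header_lines(seed, config_hash))
        df.to_csv(fh, sep=sep, na_rep=na_rep, index=index)


# ---------------------------------------------------------------------------
# genotypes (TSV)
# ---------------------------------------------------------------------------


def write_genotypes_tsv(genotypes: pd.DataFrame, path, seed=None,
                        config_hash=None) -> None:
    g = genotypes.copy()
    # integer cells where called, NA where missing
    g = g.astype("Int64")
    _write_table(g, Path(path), "\t", seed, config_hash)


def read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     na_values=["NA"], dtype=str)
    out = df.apply(pd.to_numeric, errors="coerce")
    bad_cells = out.isna() & ~df.isna()
    values = out.to_numpy(dtype=float)
    legal = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
    if bad_cells.to_numpy().any() or not legal.all():
        loc = np.argwhere(~legal | bad_cells.to_numpy())[0]
        raise ValueError(
            f"{path}: illegal genotype cell at row {out.index[loc[0]]!r}, "
            f"column {out.columns[loc[1]]!r} (must be 0/1/2/NA)"
        )
    if out.index.duplicated().any():
        raise ValueError(f"{path}: duplicate subject identifiers")
    if out.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate SNP identifiers")
    out.index.name = "subject_id"
    return out


# ---------------------------------------------------------------------------
# phenotypes (CSV)
# ---------------------------------------------------------------------------

_PHENO_REQUIRED = ("depression", "bmi", "sex", "age", "province")


def write_pheno_csv(pheno: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    _write_table(pheno, Path(path), ",", seed, config_hash)


def read_pheno(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col=0)
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype column(s) {missing}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate subject_id {dup!r}")
    dep = pd.to_numeric(df["depression"], errors="coerce")
    if not dep.isin([0, 1]).all():
        bad = df["depression"][~dep.isin([0, 1])].iloc[0]
        raise ValueError(f"{path}: depression must be 0/1, found {bad!r}")
    bmi = pd.to_numeric(df["bmi"], errors="coerce")
    if bmi.isna().any() or (bmi <= 0).any():
        raise ValueError(f"{path}: bmi must be positive numeric")
    df["depression"] = dep.astype(int)
    df["bmi"] = bmi
    df["sex"] = pd.to_numeric(df["sex"]).astype(int)
    df["age"] = pd.to_numeric(df["age"])
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# annotation (CSV)
# ---------------------------------------------------------------------------

_ANNO_REQUIRED = ("snp_id", "effect_allele", "other_allele",
                  "literature_direction", "source")


def write_annotation_csv(annotation: pd.DataFrame, path, seed=None,
                         config_hash=None) -> None:
    _write_table(annotation.reset_index(drop=True), Path(path), ",", seed,
                 config_hash, index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _ANNO_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {missing}")
    if df["snp_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate snp_id")
    if not df["literature_direction"].isin([-1, 1]).all():
        raise ValueError(f"{path}: literature_direction must be +1 or -1")
    ambiguous = [
        r.snp_id
        for r in df.itertuples()
        if frozenset({str(r.effect_allele), str(r.other_allele)}) in _AMBIGUOUS
    ]
    if ambiguous:
        warnings.warn(
            f"strand-ambiguous SNPs (A/T or C/G) loaded as-is: {ambiguous}",
            stacklevel=2,
        )
    return df.set_index("snp_id", drop=False)


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------


def read_vcf(path, annotation: pd.DataFrame) -> pd.DataFrame:
    """Load genotype dosages from a minimal VCF (biallelic, GT only).

    The dosage of each site is the count of the annotation's effect
    allele for that SNP id; ``./.`` is missing.  Multi-allelic sites and
    REF/ALT pairs that do not match the annotation alleles are errors.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows: dict[str, np.ndarray] = {}
    mismatched: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic site {variant.ID or variant.POS}"
            )
        snp_id = variant.ID
        if snp_id not in annotation.index:
            raise ValueError(f"{path}: SNP {snp_id!r} missing from annotation")
        eff = str(annotation.loc[snp_id, "effect_allele"])
        other = str(annotation.loc[snp_id, "other_allele"])
        ref, alt = variant.REF, variant.ALT[0]
        if {ref, alt} != {eff, other}:
            mismatched.append(snp_id)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = variant.genotypes
        dos = np.empty(len(subjects))
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                dos[i] = np.nan
            else:
                alt_count = sum(1 for a in alleles if a == 1)
                dos[i] = alt_count if eff == alt else len(alleles) - alt_count
        rows[snp_id] = dos
    if mismatched:
        raise ValueError(f"{path}: allele mismatch with annotation for {mismatched}")
    out = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"))
    return out


def write_vcf(genotypes: pd.DataFrame, annotation: pd.DataFrame, path,
              seed=None, config_hash=None) -> None:
    """Emit a minimal biallelic VCF (GT field only) from a dosage matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    subjects = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=depgrs {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(subjects) + "\n")
        for snp in genotypes.columns:
            row = annotation.loc[snp]
            # effect (minor) allele written as ALT
            ref, alt = str(row["other_allele"]), str(row["effect_allele"])
            chrom = str(row.get("chr", "1"))
            pos = int(row.get("pos", 1))
            gts = []
            for g in genotypes[snp]:
                if pd.isna(g):
                    gts.append("./.")
                else:
                    g = int(g)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[g])
            fh.write(
                f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )
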
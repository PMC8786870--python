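"""Per-SNP association scan, concordance selection and the unweighted GRS.

Each QC'd SNP is tested in a covariate-adjusted additive logistic model;
SNPs whose fitted effect sign matches the literature direction are kept
(significance not required), protective SNPs are flipped, and the GRS is
the integer risk-allele sum over the selected panel (complete cases
only).  Output: results/study/{snp_scan_depression.tsv, grs_selection.csv,
grs.csv} and a case/control GRS summary.
"""

from pathlib import Path

from depgrs import io
from depgrs.grs import build_grs
from depgrs.models import group_compare, univariate_snp_scan

OUT = Path("results/study")

geno = io.read_genotypes_tsv(OUT / "genotypes_qc.tsv")
pheno = io.read_pheno(OUT / "pheno_qc.csv")
anno = io.read_annotation(OUT / "annotation.csv")

scan = univariate_snp_scan(geno, pheno)
scan.to_csv(OUT / "snp_scan_depression.tsv", sep="\t", index=False)
n_nominal = int((scan["p"] < 0.05).sum())
n_fdr = int((scan["p_adj"] < 0.05).sum())
print(f"per-SNP scan: {n_nominal} nominally significant, {n_fdr} after FDR")

grs_table, selection, n_dropped = build_grs(geno, anno,
                                            scan[scan["skipped"] == ""])
selection.to_csv(OUT / "grs_selection.csv", index=False)
grs_table.to_csv(OUT / "grs.csv")
print(f"concordant SNPs: {int(selection['concordant'].sum())} of "
      f"{len(selection)}; GRS computed for {len(grs_table)} subjects "
      f"({n_dropped} dropped by the complete-case rule)")

data = pheno.join(grs_table, how="inner")
cases = data[data["depression"] == 1]["grs"]
ctrls = data[data["depression"] == 0]["grs"]
rep = group_compare(data["grs"].to_numpy(), data["depression"].to_numpy())
print(f"GRS mean (SD): cases {cases.mean():.2f} ({cases.std():.2f}), "
      f"controls {ctrls.mean():.2f} ({ctrls.std():.2f}); "
      f"Cohen's d = {abs(rep.cohens_d):.2f} ({rep.test_used}, p = {rep.p:.2e})")
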
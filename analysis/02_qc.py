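"""Marker- and subject-level QC of the simulated cohort.

Applies, in order: underweight exclusion (BMI <= 18.5), call rate >= 95%,
MAF >= 0.05, exact HWE in controls at alpha 0.05, LD pruning at R^2 > 0.8.
Output: results/study/{qc_report.tsv, genotypes_qc.tsv, pheno_qc.csv}.
"""

import json
from pathlib import Path

from depgrs import io
from depgrs.qc import QcConfig, run_qc

OUT = Path("results/study")

geno = io.read_genotypes_tsv(OUT / "genotypes.tsv")
pheno = io.read_pheno(OUT / "pheno.csv")

res = run_qc(geno, pheno, QcConfig())
res.report().to_csv(OUT / "qc_report.tsv", sep="\t")
io.write_genotypes_tsv(res.genotypes, OUT / "genotypes_qc.tsv")
io.write_pheno_csv(res.pheno, OUT / "pheno_qc.csv")

print(json.dumps(res.counts, indent=2))
print(f"{res.counts['snps_in']} -> {res.counts['snps_out']} SNPs; "
      f"{res.counts['subjects_in']} -> {res.counts['subjects_out']} subjects")
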
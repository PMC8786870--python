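"""End-to-end orchestration: simulate/load -> QC -> GRS -> models -> metrics.

``run_all`` executes the stages in order, writes every stage output under
the configured directory and returns a :class:`RunManifest` whose
stage-wise subject/SNP counts reconcile.  Identical configuration and
seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .grs import build_grs
from .metrics import evaluate_model_suite, kfold_cv, reports_to_table, roc_auc
from .models import (
    grs_quartile_contrasts,
    interaction_grid,
    interaction_model,
    univariate_snp_scan,
)
from .qc import QcConfig, run_qc
from .simulate import simulate_study

log = logging.getLogger("depgrs")

__all__ = ["RunConfig", "RunManifest", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 1
    # either simulate ...
    simulate: bool = True
    n_subjects: int = 1650
    n_snps: int = 56
    prevalence: float = 104 / 1650
    or_per_allele: float = 1.35
    gamma_interaction_or: float = 1.14
    discordant_fraction: float = 0.46
    missing_rate: float = 0.0
    underweight_rate: float = 0.0
    # ... or load from files
    genotype_path: str | None = None
    pheno_path: str | None = None
    annotation_path: str | None = None
    genotype_dialect: str = "tsv"  # or "vcf"
    # analysis settings
    qc: QcConfig = field(default_factory=QcConfig)
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    nri_cuts: tuple[float, float] = (0.05, 0.25)
    run_cv: bool = False
    cv_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc_raw = raw.pop("qc", None)
        cfg = cls(**raw)
        if qc_raw:
            cfg.qc = QcConfig(**qc_raw)
        for name in ("genotype_path", "pheno_path", "annotation_path"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} points to missing file {p}")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # identifies the analysis, not its location
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    started: float
    finished: float | None = None
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _write_table(df: pd.DataFrame, path: Path, seed: int, config_hash: str,
                 sep: str = ",", index: bool = True) -> None:
    """Tabular stage output with the version/seed/hash comment header."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(io.header_lines(seed, config_hash))
        df.to_csv(fh, sep=sep, index=index)


def _write_json(payload: dict, path: Path, seed: int, config_hash: str) -> None:
    payload = {"_meta": {"version": __version__, "seed": seed,
                         "config_hash": config_hash}, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def _load_inputs(config: RunConfig):
    if config.simulate:
        study = simulate_study(
            n_subjects=config.n_subjects,
            n_snps=config.n_snps,
            seed=config.seed,
            prevalence=config.prevalence,
            or_per_allele=config.or_per_allele,
            interaction_or=config.gamma_interaction_or,
            discordant_fraction=config.discordant_fraction,
            missing_rate=config.missing_rate,
            underweight_rate=config.underweight_rate,
        )
        return study.genotypes, study.pheno, study.annotation
    anno = io.read_annotation(config.annotation_path)
    pheno = io.read_pheno(config.pheno_path)
    if config.genotype_dialect == "vcf":
        geno = io.read_vcf(config.genotype_path, anno)
    else:
        geno = io.read_genotypes_tsv(config.genotype_path)
    geno = geno.loc[pheno.index]
    return geno, pheno, anno


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full analysis and write all stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest = RunManifest(
        version=__version__, seed=config.seed, config_hash=chash,
        started=time.time(),
    )
    meta = dict(seed=config.seed, config_hash=chash)

    geno, pheno, anno = _load_inputs(config)
    manifest.counts["subjects_input"] = len(pheno)
    manifest.counts["snps_input"] = geno.shape[1]
    log.info("loaded %d subjects x %d SNPs", len(pheno), geno.shape[1])
    if config.simulate:
        io.write_genotypes_tsv(geno, out / "genotypes.tsv", **meta)
        io.write_pheno_csv(pheno, out / "pheno.csv", **meta)
        io.write_annotation_csv(anno, out / "annotation.csv", **meta)

    # QC
    qc_res = run_qc(geno, pheno, config.qc)
    manifest.counts.update(qc_res.counts)
    _write_table(qc_res.report(), out / "qc_report.tsv", config.seed, chash,
                 sep="\t")
    io.write_genotypes_tsv(qc_res.genotypes, out / "genotypes_qc.tsv", **meta)
    log.info(
        "QC: %d -> %d SNPs, %d -> %d subjects",
        qc_res.counts["snps_in"], qc_res.counts["snps_out"],
        qc_res.counts["subjects_in"], qc_res.counts["subjects_out"],
    )

    # per-SNP scan on depression
    scan = univariate_snp_scan(qc_res.genotypes, qc_res.pheno)
    _write_table(scan, out / "snp_scan_depression.tsv", config.seed, chash,
                 sep="\t", index=False)

    # GRS
    grs_table, selection, n_dropped = build_grs(
        qc_res.genotypes, anno, scan[scan["skipped"] == ""]
    )
    manifest.counts["snps_selected_concordant"] = int(
        selection["concordant"].sum()
    )
    manifest.counts["subjects_dropped_incomplete_grs"] = n_dropped
    manifest.counts["subjects_grs"] = len(grs_table)
    _write_table(selection, out / "grs_selection.csv", config.seed, chash,
                 index=False)
    _write_table(grs_table, out / "grs.csv", config.seed, chash)
    log.info(
        "GRS: %d concordant SNPs of %d; %d subjects (%d dropped, incomplete)",
        manifest.counts["snps_selected_concordant"], len(selection),
        len(grs_table), n_dropped,
    )

    # association models
    data = qc_res.pheno.join(grs_table, how="inner")
    quart = grs_quartile_contrasts(data)
    inter = interaction_model(data)
    grid = interaction_grid(inter, data)
    _write_table(grid, out / "interaction_grid.csv", config.seed, chash,
                 index=False)
    summaries = {
        "quartile_contrasts": quart.params.to_dict(orient="index"),
        "interaction_model": inter.params.to_dict(orient="index"),
        "interaction_d_squared": inter.d_squared,
        "n_used": inter.n_used,
    }
    _write_json(summaries, out / "model_summaries.json", config.seed, chash)

    # evaluation
    fits, reports = evaluate_model_suite(data, cuts=config.nri_cuts)
    table = reports_to_table(reports)
    _write_table(table, out / "model_improvement.tsv", config.seed, chash,
                 sep="\t")
    auc_rows = {
        f"model_{m}": {
            "auc": roc_auc(f.fitted_prob, data.loc[f.fitted_prob.index, "depression"])[0],
            "d_squared": f.d_squared,
            "n": f.n_used,
        }
        for m, f in fits.items()
    }
    _write_json(auc_rows, out / "model_auc.json", config.seed, chash)

    if config.run_cv:
        cv = kfold_cv(data, k=config.cv_k, seed=config.seed, cuts=config.nri_cuts)
        cv_payload = {
            "k": cv.k,
            "seed": cv.seed,
            "mean_auc": cv.mean_auc.to_dict(),
            "mean_metrics": cv.mean_metrics.to_dict(),
        }
        _write_json(cv_payload, out / "cv_report.json", config.seed, chash)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
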
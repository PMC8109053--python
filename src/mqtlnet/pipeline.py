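"""End-to-end pipeline driver.

Chains the full analysis: QC/normalization -> phenotype-metabolite
associations -> met-QTL scan -> recursive conditioning -> variance
decomposition -> GGM -> phenotype modules -> enrichment, writing every
intermediate table and a run report whose counts mirror the stage
outputs (metabolites retained, subjects removed, significant
associations, met-QTL pairs, independent SNPs, network size, modules).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, enrich, io, network, qc, qtl
from .containers import association_frame

log = logging.getLogger("mqtlnet")


@dataclass
class RunConfig:
    abundance: str | None = None
    genotypes: str | None = None
    genotype_metadata: str | None = None
    phenotypes: str | None = None
    annotation: str | None = None
    out_dir: str = "mqtlnet_run"
    seed: int = 0
    max_missing: float = 0.20
    knn_k: int = 10
    outlier_z: float = 3.5
    assoc_alpha: float = 0.05
    scan_alpha: float = 0.05
    min_maf: float = 0.01
    n_ancestry_pcs: int = 5
    ggm_alpha: float = 0.05
    pcor_min: float = 0.2
    module_alpha: float = 0.05
    phenotype_names: tuple = ("fev1pp", "fev1_fvc", "pct_emphysema",
                              "exacerbation_count", "chronic_bronchitis")
    run_genetics: bool = True

    def validate(self) -> None:
        for name in ("abundance", "phenotypes"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing or not found: {p}")
        if self.run_genetics and (
            self.genotypes is None or not Path(self.genotypes).exists()
        ):
            raise FileNotFoundError(f"genotypes path missing: {self.genotypes}")


def _covariate_design(cov: pd.DataFrame, n_pcs: int) -> pd.DataFrame:
    cols = [c for c in assoc.DEFAULT_COVARIATES if c in cov.columns]
    cols += [f"pc{k + 1}" for k in range(n_pcs) if f"pc{k + 1}" in cov.columns]
    return assoc.build_design(cov, cols).drop(columns="const")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run report dict."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    stage = "load"
    try:
        raw = io.read_abundance(cfg.abundance)
        pheno, cov = io.read_phenotypes(cfg.phenotypes)
        common = raw.values.index.intersection(pheno.index)
        dropped = len(raw.values.index) + len(pheno.index) - 2 * len(common)
        if len(common) == 0:
            raise ValueError("zero sample overlap between abundance and phenotypes")
        if dropped:
            log.warning("dropped %d non-overlapping samples", dropped)
        report["n_samples_loaded"] = int(len(common))
        report["n_metabolites_loaded"] = raw.n_metabolites

        stage = "qc"
        clean, qc_report = qc.preprocess(
            raw, max_missing=cfg.max_missing, k=cfg.knn_k, z_cut=cfg.outlier_z
        )
        io.write_abundance(clean, out / "abundance_transformed.tsv",
                           meta={"seed": cfg.seed})
        io.write_table(qc_report.removed_metabolites, out / "qc_removed_metabolites.tsv")
        io.write_table(qc_report.removed_subjects, out / "qc_removed_subjects.tsv")
        report["n_metabolites_retained"] = clean.n_metabolites
        report["n_subjects_removed"] = int(len(qc_report.removed_subjects))
        pheno = pheno.loc[pheno.index.intersection(clean.values.index)]
        cov = cov.loc[clean.values.index.intersection(cov.index)]

        stage = "assoc"
        records = []
        for name in cfg.phenotype_names:
            if name not in pheno.columns:
                continue
            records.extend(
                assoc.fit_metabolite_phenotype(
                    clean, pheno, cov, name, alpha=cfg.assoc_alpha
                )
            )
        assoc_df = association_frame(records)
        io.write_table(assoc_df, out / "phenotype_associations.tsv",
                       meta={"alpha": cfg.assoc_alpha,
                             "bonferroni": cfg.assoc_alpha / clean.n_metabolites})
        report["n_assoc_tests"] = int(len(assoc_df))
        report["n_assoc_significant"] = int(assoc_df["significant"].sum())
        report["n_metabolites_phenotype_associated"] = int(
            assoc_df.loc[assoc_df["significant"], "metabolite"].nunique()
        )

        ind_sets: dict = {}
        if cfg.run_genetics:
            stage = "mwas"
            geno = io.read_genotypes(cfg.genotypes, cfg.genotype_metadata)
            geno = qtl.maf_filter(geno, cfg.min_maf)
            report["n_snps_after_maf"] = geno.n_snps
            design = _covariate_design(cov, cfg.n_ancestry_pcs)
            scan = qtl.metqtl_scan(clean, geno, design, alpha=cfg.scan_alpha)
            io.write_table(scan.records, out / "metqtl_scan.tsv",
                           meta={"threshold": scan.threshold, "n": scan.n_samples})
            sig = scan.records[scan.records["significant"]]
            report["n_metqtl_pairs"] = int(len(sig))
            report["n_metqtl_snps"] = int(sig["snp"].nunique())
            report["n_metqtl_metabolites"] = int(sig["metabolite"].nunique())

            stage = "condition"
            ind_sets = qtl.condition_all(clean, geno, design, scan)
            rows = [
                {"metabolite": met, "snp": s, "conditional_p": p, "rank": i}
                for met, ind in ind_sets.items()
                for i, (s, p) in enumerate(zip(ind.snps, ind.conditional_p))
            ]
            ind_df = pd.DataFrame(rows, columns=["metabolite", "snp",
                                                 "conditional_p", "rank"])
            io.write_table(ind_df, out / "independent_metqtls.tsv")
            report["n_independent_snps"] = int(ind_df["snp"].nunique()) if len(ind_df) else 0

            stage = "vardecomp"
            decomp_rows = []
            for met, ind in ind_sets.items():
                vd = qtl.variance_explained(clean, geno, design, ind)
                for snp, inc in zip(vd.snp_ids, vd.snp_r2_increments):
                    decomp_rows.append(
                        {"metabolite": met, "snp": snp, "r2_increment": inc,
                         "r2_covariates": vd.r2_covariates,
                         "r2_genetic": vd.r2_genetic}
                    )
            decomp_df = pd.DataFrame(
                decomp_rows, columns=["metabolite", "snp", "r2_increment",
                                      "r2_covariates", "r2_genetic"]
            )
            io.write_table(decomp_df, out / "variance_decomposition.tsv")

        stage = "ggm"
        conf_cols = [c for c in assoc.DEFAULT_COVARIATES if c in cov.columns]
        net = network.estimate_ggm(
            clean, cov[conf_cols], alpha=cfg.ggm_alpha, pcor_min=cfg.pcor_min
        )
        full_net = network.add_snp_nodes(net, ind_sets)
        io.export_graphml(full_net, out / "network.graphml")
        io.export_sif(full_net, out / "network.sif")
        n_met, n_snp, n_edges = network.network_summary(full_net)
        report["network_metabolite_nodes"] = n_met
        report["network_snp_nodes"] = n_snp
        report["network_edges"] = n_edges

        stage = "modules"
        module_rows = []
        all_modules = []
        for name in cfg.phenotype_names:
            if name not in pheno.columns:
                continue
            resid = network.residualize_phenotype(pheno[name], cov[conf_cols])
            mods = network.greedy_module_search(
                net, clean, resid, phenotype=name, alpha=cfg.module_alpha
            )
            all_modules.extend(mods)
            for i, mod in enumerate(mods):
                row = {
                    "phenotype": name,
                    "module_id": i,
                    "members": ";".join(mod.members),
                    "module_beta": mod.beta,
                    "score": mod.score,
                    "adjusted_score": mod.adjusted_score,
                }
                if cfg.run_genetics and mod.size >= 2:
                    mvd = network.module_variance_decomposition(
                        mod, clean, geno, ind_sets, cov[conf_cols]
                    )
                    row["r2_genetic"] = mvd.r2_genetic
                    row["r2_covariates"] = mvd.r2_covariates
                module_rows.append(row)
        mod_df = pd.DataFrame(module_rows)
        io.write_table(mod_df, out / "phenotype_modules.tsv")
        report["n_modules"] = len(all_modules)

        stage = "enrichment"
        if cfg.annotation is not None and Path(cfg.annotation).exists():
            ann = io.read_annotation(cfg.annotation)
            sub_map = ann.subpathway_map()
            sig_mets = set(assoc_df.loc[assoc_df["significant"], "metabolite"])
            if sig_mets:
                enr = enrich.fisher_enrichment(
                    sig_mets, set(clean.metabolite_ids), sub_map
                )
                io.write_table(enr, out / "enrichment_subpathway.tsv")
                report["n_enriched_groups"] = int(enr["significant"].sum())
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        report["failed_stage"] = stage
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
        raise
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return report
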
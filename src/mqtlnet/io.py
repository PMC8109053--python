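"""File formats: TSV tables, VCF dosages, GraphML/SIF network export.

All tabular outputs are TSV with '#'-prefixed metadata header lines.
Abundance tables have samples in rows, metabolites in columns, a first
column ``sample`` and a reserved column ``runday``; missing cells are
empty strings or "NA".  Genotypes come from a VCF (DS field preferred,
GT allele count otherwise) or from a TSV dosage matrix with a sidecar
SNP metadata TSV.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, DosageMatrix

PHENOTYPE_COLUMNS = ("fev1pp", "fev1_fvc", "pct_emphysema",
                     "exacerbation_count", "chronic_bronchitis")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["", "NA"],
                       keep_default_na=True, **kw)


def write_table(df: pd.DataFrame, path, meta: dict | None = None, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def _header_fields(path) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return line.rstrip("\n").split("\t")
    return []


def read_abundance(path, stage: str = "raw") -> AbundanceMatrix:
    header = _header_fields(path)
    met_cols = [c for c in header if c not in ("sample", "runday")]
    if len(set(met_cols)) != len(met_cols):
        dup = sorted({c for c in met_cols if met_cols.count(c) > 1})
        raise ValueError(f"duplicate metabolite ids: {dup[:5]}")
    df = _read_tsv(path)
    if "sample" not in df.columns or "runday" not in df.columns:
        raise ValueError("abundance TSV needs 'sample' and 'runday' columns")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in abundance table")
    df = df.set_index("sample")
    df.index.name = None
    runday = df.pop("runday").astype(str)
    return AbundanceMatrix(df.astype(float), runday, stage=stage)


def write_abundance(m: AbundanceMatrix, path, meta: dict | None = None) -> None:
    df = m.values.copy()
    df.insert(0, "runday", m.runday)
    df.index.name = "sample"
    meta = {"stage": m.stage, **(meta or {})}
    write_table(df.reset_index(), path, meta=meta)


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sample-keyed TSV into (phenotypes, covariates)."""
    df = _read_tsv(path)
    if "sample" not in df.columns:
        raise ValueError("phenotype TSV needs a 'sample' column")
    df = df.set_index("sample")
    df.index.name = None
    pheno_cols = [c for c in PHENOTYPE_COLUMNS if c in df.columns]
    cov_cols = [c for c in df.columns if c not in pheno_cols]
    return df[pheno_cols], df[cov_cols]


def write_phenotypes(pheno: pd.DataFrame, cov: pd.DataFrame, path,
                     meta: dict | None = None) -> None:
    df = pd.concat([pheno, cov], axis=1)
    df.index.name = "sample"
    write_table(df.reset_index(), path, meta=meta)


def read_annotation(path):
    from .containers import MetaboliteAnnotation

    return MetaboliteAnnotation(_read_tsv(path))


def read_genotypes(path, metadata: str | Path | None = None) -> DosageMatrix:
    """Load dosages from a VCF (.vcf) or a TSV dosage matrix.

    For TSV input, per-SNP metadata (chrom, pos, alleles, consequence,
    nearest gene) comes from the sidecar ``metadata`` TSV keyed by snp
    id; without one, minimal metadata is synthesized from the dosages.
    """
    path = Path(path)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        return _read_vcf(path)
    df = _read_tsv(path)
    if "sample" not in df.columns:
        raise ValueError("dosage TSV needs a 'sample' column")
    df = df.set_index("sample").astype(float)
    df.index.name = None
    if metadata is not None:
        info = _read_tsv(metadata).set_index("snp")
    else:
        info = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, df.shape[1] + 1) * 1000,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": df.mean(axis=0).to_numpy() / 2,
                "consequence": "",
                "nearest_gene": "",
            },
            index=pd.Index(df.columns, name="snp"),
        )
    return DosageMatrix(df, info)


def _read_vcf(path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows_info = [], []
    data = []
    for i, var in enumerate(vcf):
        try:
            try:
                ds = var.format("DS")
            except KeyError:  # record lacks a DS field entirely
                ds = None
            if ds is not None:
                dos = np.asarray(ds, dtype=float).reshape(len(samples))
            else:
                gt = np.asarray(var.gt_types)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
                dos = np.where(gt == 3, 2.0, np.where(gt == 1, 1.0, 0.0))
                dos = np.where(gt == 2, np.nan, dos)
        except Exception as exc:
            raise ValueError(f"malformed VCF record at line {i + 1}: {exc}") from exc
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        cols.append(vid)
        data.append(dos)
        rows_info.append(
            {
                "snp": vid,
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": var.ALT[0] if var.ALT else ".",
                "other_allele": var.REF,
                "eaf": float(np.nanmean(dos) / 2),
                "consequence": (var.INFO.get("CSQ") or ""),
                "nearest_gene": (var.INFO.get("GENE") or ""),
            }
        )
    dosages = pd.DataFrame(np.column_stack(data), index=samples, columns=cols)
    info = pd.DataFrame(rows_info).set_index("snp")
    return DosageMatrix(dosages, info)


def write_genotypes_tsv(g: DosageMatrix, dosage_path, metadata_path,
                        meta: dict | None = None) -> None:
    df = g.dosages.copy()
    df.index.name = "sample"
    write_table(df.reset_index(), dosage_path, meta=meta)
    info = g.snp_info.copy()
    info.index.name = "snp"
    write_table(info.reset_index(), metadata_path, meta=meta)


def write_genotypes_vcf(g: DosageMatrix, path) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(g.dosages.index)
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
    for c in sorted({str(c) for c in g.snp_info["chrom"]}):
        buf.write(f"##contig=<ID={c}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(samples) + "\n")
    info = g.snp_info
    order = info.sort_values(["chrom", "pos"]).index
    for snp in order:
        row = info.loc[snp]
        dos = g.dosages[snp]
        fields = []
        for d in dos:
            if np.isnan(d):
                fields.append("./.:.")
            else:
                hard = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(hard, 0), 2)]
                fields.append(f"{gt}:{d:g}")
        buf.write(
            f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['other_allele']}\t"
            f"{row['effect_allele']}\t.\t.\t.\tGT:DS\t" + "\t".join(fields) + "\n"
        )
    path.write_text(buf.getvalue())


def export_graphml(G: nx.Graph, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(G, str(path))


def export_sif(G: nx.Graph, path) -> None:
    """Simple interaction format: node <relation> node, one edge per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for u, v, d in G.edges(data=True):
            fh.write(f"{u}\t{d.get('provenance', 'ggm')}\t{v}\n")
        for node in nx.isolates(G):
            fh.write(f"{node}\n")
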
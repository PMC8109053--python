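"""Core in-memory containers shared across the pipeline.

The abundance and dosage containers are thin wrappers around pandas
DataFrames that carry the metadata the analysis stages need (run-day
labels, SNP annotation, processing stage) and enforce the stage ordering
of the pre-analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Pre-analysis stages, in the only order transitions are allowed.
STAGES = ("raw", "normalized", "filtered", "imputed", "transformed")


class StageError(RuntimeError):
    """Raised when a pre-analysis operation is called out of order."""


@dataclass
class AbundanceMatrix:
    """Sample x metabolite intensities with run-day labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per metabolite id.
        Missing cells are NaN.  Intensities are non-negative at every
        stage before ``transformed``.
    runday
        Per-sample run-day (batch) label, aligned to ``values.index``.
    stage
        One of :data:`STAGES`.
    """

    values: pd.DataFrame
    runday: pd.Series
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate metabolite ids")
        self.runday = self.runday.reindex(self.values.index)
        if self.runday.isna().any():
            missing = self.runday.index[self.runday.isna()].tolist()
            raise ValueError(f"samples without run-day label: {missing[:5]}")
        if self.stage != "transformed":
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("negative intensities before transformation")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is at "
                f"{self.stage!r}; the pre-analysis order is "
                + " -> ".join(STAGES)
            )

    def advance(self, values: pd.DataFrame, stage: str) -> "AbundanceMatrix":
        """Return a new matrix at ``stage``, checking the transition order."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move back from {self.stage!r} to {stage!r}")
        return AbundanceMatrix(values, self.runday.loc[values.index], stage)


@dataclass
class MetaboliteAnnotation:
    """Per-metabolite pathway annotation (one row per metabolite id)."""

    table: pd.DataFrame  # columns: metabolite, name, super_pathway, subpathway, annotated

    REQUIRED = ("metabolite", "super_pathway", "subpathway", "annotated")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"annotation table lacks column {col!r}")
        if self.table["metabolite"].duplicated().any():
            raise ValueError("duplicate metabolite ids in annotation")

    def subpathway_map(self) -> dict:
        return dict(zip(self.table["metabolite"], self.table["subpathway"]))

    def super_pathway_map(self) -> dict:
        return dict(zip(self.table["metabolite"], self.table["super_pathway"]))


@dataclass
class DosageMatrix:
    """Sample x SNP additive dosages in [0, 2] plus per-SNP metadata.

    ``snp_info`` is indexed by SNP id with columns chrom, pos, effect_allele,
    other_allele, eaf, consequence, nearest_gene (annotation columns may be
    empty strings when unknown).
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.is_unique:
            raise ValueError("duplicate SNP ids")
        missing = [s for s in self.dosages.columns if s not in self.snp_info.index]
        if missing:
            raise ValueError(f"SNPs without metadata: {missing[:5]}")
        arr = self.dosages.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def snp_ids(self) -> list:
        return list(self.dosages.columns)

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> pd.Series:
        """Effect-allele frequency from the analysis sample (mean dosage / 2)."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0


@dataclass
class QCReport:
    """What quality control removed and why."""

    removed_metabolites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["metabolite", "missing_fraction"])
    )
    removed_subjects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "median_z"])
    )
    runday_shift: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["runday", "pre_median", "post_median"])
    )
    notes: list = field(default_factory=list)

    def log(self, message: str) -> None:
        self.notes.append(message)


@dataclass
class AssociationRecord:
    """One metabolite-phenotype (or metabolite-demographic) test."""

    metabolite: str
    phenotype: str
    family: str
    beta: float
    se: float
    p: float
    significant: bool
    n: int
    converged: bool = True


def association_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "phenotype": r.phenotype,
                "family": r.family,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "significant": r.significant,
                "n": r.n,
                "converged": r.converged,
            }
            for r in records
        ]
    )
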
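"""Synthetic COPD cohort generator with a planted-truth registry.

Emulates the statistical structure the analysis pipeline assumes: a
smoking-enriched cohort with spirometry/CT phenotypes, non-negative
skewed metabolite intensities measured over multiple instrument run
days, additive SNP effects of controlled variance explained, covariate
effects, block-correlated metabolite modules tied to phenotypes,
missing-at-random dropout, and gross subject-level outliers.

Metabolite intensities are log-normal: a latent Gaussian with unit
variance is assembled from the planted components and exponentiated,
then multiplied by a per-run-day batch factor.  The rank-based
inverse-normal transform applied downstream makes the exact marginal
irrelevant; what matters is the correlation structure, which is planted
exactly on the latent scale.

Every planted effect is recorded in a :class:`SyntheticTruth` registry
so each downstream stage has a recovery test against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, DosageMatrix

PHENOTYPES = ("fev1pp", "fev1_fvc", "pct_emphysema", "exacerbation_count", "chronic_bronchitis")
COVARIATES = ("age", "sex", "bmi", "current_smoker", "pack_years", "center")


@dataclass(frozen=True)
class PlantedQTL:
    metabolite: int
    snp: int
    eaf: float
    r2: float


@dataclass(frozen=True)
class PlantedModule:
    members: tuple
    rho: float  # intra-module latent correlation
    phenotype: str
    effect: float  # per-member standardized correlation with the phenotype latent


@dataclass(frozen=True)
class CovariateEffect:
    """A covariate influencing a random subset of metabolites.

    ``effect`` is the standardized per-metabolite coefficient (so the
    covariate explains ``effect**2`` of an affected metabolite's latent
    variance); ``fraction`` is the share of metabolites affected.
    """

    effect: float
    fraction: float = 1.0


@dataclass(frozen=True)
class LDPair:
    """Two SNPs in linkage disequilibrium (haplotype-copy correlation r)."""

    parent: int
    child: int
    r: float


@dataclass
class SimulationConfig:
    n_subjects: int = 500
    n_metabolites: int = 200
    n_snps: int = 2000
    n_rundays: int = 10
    missing_rate: float = 0.02
    n_outlier_subjects: int = 0
    planted_qtls: Sequence[PlantedQTL] = ()
    planted_modules: Sequence[PlantedModule] = ()
    covariate_effects: Mapping[str, CovariateEffect] = field(default_factory=dict)
    ld_pairs: Sequence[LDPair] = ()
    runday_scale: float = 0.15  # log-SD of the multiplicative batch factor
    per_metabolite_runday: bool = False
    n_ancestry_pcs: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_subjects", "n_metabolites", "n_snps", "n_rundays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_outlier_subjects < 0 or self.n_outlier_subjects > self.n_subjects:
            raise ValueError("n_outlier_subjects out of range")
        budget = np.zeros(self.n_metabolites)
        for q in self.planted_qtls:
            if not 0 <= q.metabolite < self.n_metabolites:
                raise ValueError(f"planted QTL metabolite index {q.metabolite} out of range")
            if not 0 <= q.snp < self.n_snps:
                raise ValueError(f"planted QTL SNP index {q.snp} out of range")
            if not 0.01 < q.eaf < 0.99:
                raise ValueError("planted QTL EAF must be in (0.01, 0.99)")
            if not 0 <= q.r2 < 1:
                raise ValueError("planted QTL r2 must be in [0, 1)")
            budget[q.metabolite] += q.r2
        seen = set()
        for mod in self.planted_modules:
            if mod.phenotype not in PHENOTYPES:
                raise ValueError(f"unknown phenotype {mod.phenotype!r}")
            if not 0 < mod.rho < 1:
                raise ValueError("intra-module correlation must be in (0, 1)")
            if abs(mod.effect) > np.sqrt(mod.rho):
                raise ValueError(
                    "per-member effect cannot exceed sqrt(intra-module correlation)"
                )
            for m in mod.members:
                if not 0 <= m < self.n_metabolites:
                    raise ValueError(f"module metabolite index {m} out of range")
                if m in seen:
                    raise ValueError(f"metabolite {m} belongs to more than one module")
                seen.add(m)
                budget[m] += mod.rho
        for cov, eff in self._covariate_effects().items():
            if cov not in COVARIATES:
                raise ValueError(f"unknown covariate {cov!r}")
            budget += eff.effect**2 * eff.fraction  # upper bound; exact check below
        for pair in self.ld_pairs:
            if not (0 <= pair.parent < self.n_snps and 0 <= pair.child < self.n_snps):
                raise ValueError("LD pair SNP index out of range")
            if not 0 <= pair.r <= 1:
                raise ValueError("LD r must be in [0, 1]")
        bad = np.flatnonzero(budget >= 1)
        if bad.size:
            raise ValueError(
                f"infeasible variance budget for metabolite index {bad[0]}: "
                f"planted fractions sum to {budget[bad[0]]:.3f} >= 1"
            )

    def _covariate_effects(self) -> dict:
        out = {}
        for cov, eff in self.covariate_effects.items():
            out[cov] = eff if isinstance(eff, CovariateEffect) else CovariateEffect(float(eff))
        return out


@dataclass
class SyntheticTruth:
    """Immutable registry of every planted effect in a generated cohort."""

    qtls: tuple
    modules: tuple
    outlier_subjects: tuple
    covariate_assignments: dict  # covariate -> {metabolite id: signed effect}
    realized_qtl_r2: dict  # (metabolite id, snp id) -> r2 on the latent scale
    latent: pd.DataFrame  # pre-noise-masking latent values, for oracle checks
    seed: int = 0

    def qtl_for(self, metabolite: str):
        return [q for q in self.qtls if q[0] == metabolite]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _draw_covariates(rng: np.random.Generator, n: int, n_pcs: int) -> pd.DataFrame:
    cov = pd.DataFrame(index=[f"S{i:05d}" for i in range(n)])
    cov["age"] = np.clip(rng.normal(68.3, 8.4, n), 45, 90).round(1)
    cov["sex"] = rng.binomial(1, 0.512, n)
    cov["bmi"] = np.clip(rng.normal(29.1, 6.2, n), 15, 55).round(1)
    cov["current_smoker"] = rng.binomial(1, 0.213, n)
    cov["pack_years"] = np.clip(rng.normal(46.0, 24.9, n), 0, None).round(1)
    cov["center"] = rng.choice(["C1", "C2", "C3"], n)
    for k in range(n_pcs):
        cov[f"pc{k + 1}"] = rng.normal(0, 1, n)
    return cov


def _draw_genotypes(cfg: SimulationConfig, rng: np.random.Generator) -> tuple:
    n, s = cfg.n_subjects, cfg.n_snps
    eaf = rng.uniform(0.05, 0.5, s)
    for q in cfg.planted_qtls:
        eaf[q.snp] = q.eaf
    # haplotype-level simulation so LD pairs have a defined copy correlation
    hap = np.empty((2, n, s), dtype=np.int8)
    for a in range(2):
        hap[a] = (rng.random((n, s)) < eaf).astype(np.int8)
    for pair in cfg.ld_pairs:
        eaf[pair.child] = eaf[pair.parent]
        for a in range(2):
            copy = rng.random(n) < pair.r
            fresh = (rng.random(n) < eaf[pair.parent]).astype(np.int8)
            hap[a, :, pair.child] = np.where(copy, hap[a, :, pair.parent], fresh)
    dos = hap.sum(axis=0).astype(float)
    return dos, eaf


def _phenotype_latents(cfg: SimulationConfig, rng: np.random.Generator,
                       factors: dict) -> np.ndarray:
    """One standard-normal latent per phenotype, loaded on module factors."""
    n = cfg.n_subjects
    z = np.empty((n, len(PHENOTYPES)))
    for j, pheno in enumerate(PHENOTYPES):
        loadings = []
        for mi, mod in enumerate(cfg.planted_modules):
            if mod.phenotype == pheno:
                # member-phenotype correlation = sqrt(rho) * loading = effect
                loadings.append((mi, mod.effect / np.sqrt(mod.rho)))
        var = sum(a**2 for _, a in loadings)
        if var >= 1:
            raise ValueError(f"phenotype {pheno!r} module loadings exceed unit variance")
        zj = rng.normal(0, 1, n) * np.sqrt(1 - var)
        for mi, a in loadings:
            zj += a * factors[mi]
        z[:, j] = zj
    return z


def _phenotypes_from_latents(z: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    df = pd.DataFrame()
    df["fev1pp"] = np.clip(76.6 + 26.5 * z[:, 0], 10, 150).round(1)
    df["fev1_fvc"] = np.clip(0.68 + 0.10 * z[:, 1], 0.2, 0.95).round(3)
    df["pct_emphysema"] = np.clip(7.3 + 10.2 * z[:, 2], 0, 100).round(2)
    df["exacerbation_count"] = rng.poisson(np.exp(-0.8 + 0.6 * z[:, 3]))
    df["chronic_bronchitis"] = rng.binomial(1, 1 / (1 + np.exp(-(-1.5 + 0.8 * z[:, 4]))))
    return df


def generate_cohort(cfg: SimulationConfig):
    """Generate one synthetic cohort.

    Returns
    -------
    (AbundanceMatrix, DosageMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth)
        Raw abundance matrix (with batch effects, missingness and
        outliers applied), dosage matrix with SNP metadata, covariate
        table, phenotype table, and the planted-truth registry.  The
        same config and seed reproduce all five outputs bit-identically.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_subjects, cfg.n_metabolites
    sample_ids = [f"S{i:05d}" for i in range(n)]
    met_ids = [f"M{j:04d}" for j in range(p)]
    snp_ids = [f"snp{k:05d}" for k in range(cfg.n_snps)]

    cov = _draw_covariates(rng, n, cfg.n_ancestry_pcs)
    cov.index = sample_ids
    dos, eaf = _draw_genotypes(cfg, rng)

    # module latent factors
    factors = {mi: rng.normal(0, 1, n) for mi in range(len(cfg.planted_modules))}

    # covariate effect assignment: random subset of metabolites, random sign
    cov_std = {
        "age": _standardize(cov["age"].to_numpy()),
        "sex": _standardize(cov["sex"].to_numpy(dtype=float)),
        "bmi": _standardize(cov["bmi"].to_numpy()),
        "current_smoker": _standardize(cov["current_smoker"].to_numpy(dtype=float)),
        "pack_years": _standardize(cov["pack_years"].to_numpy()),
        "center": _standardize((cov["center"] == "C1").to_numpy(dtype=float)),
    }
    assignments: dict = {}
    explained = np.zeros(p)
    cov_term = np.zeros((n, p))
    for cname, eff in cfg._covariate_effects().items():
        affected = rng.random(p) < eff.fraction
        signs = rng.choice([-1.0, 1.0], p)
        betas = np.where(affected, signs * eff.effect, 0.0)
        cov_term += np.outer(cov_std[cname], betas)
        explained += betas**2
        assignments[cname] = {
            met_ids[j]: float(betas[j]) for j in np.flatnonzero(affected)
        }

    # planted SNP effects on the standardized-dosage scale
    qtl_term = np.zeros((n, p))
    for q in cfg.planted_qtls:
        g = _standardize(dos[:, q.snp])
        qtl_term[:, q.metabolite] += np.sqrt(q.r2) * g
        explained[q.metabolite] += q.r2

    mod_term = np.zeros((n, p))
    for mi, mod in enumerate(cfg.planted_modules):
        for m in mod.members:
            mod_term[:, m] += np.sqrt(mod.rho) * factors[mi]
            explained[m] += mod.rho

    noise_sd = np.sqrt(np.clip(1.0 - explained, 1e-9, None))
    latent = cov_term + qtl_term + mod_term + rng.normal(0, 1, (n, p)) * noise_sd

    realized = {}
    for q in cfg.planted_qtls:
        r = np.corrcoef(dos[:, q.snp], latent[:, q.metabolite])[0, 1]
        realized[(met_ids[q.metabolite], snp_ids[q.snp])] = float(r**2)

    # outlier subjects: shifted >=5 within-metabolite latent SDs on 80% of metabolites
    outliers = tuple(
        sample_ids[i]
        for i in rng.choice(n, size=cfg.n_outlier_subjects, replace=False)
    )
    for sid in outliers:
        i = sample_ids.index(sid)
        hit = rng.random(p) < 0.8
        latent[i, hit] += 6.0

    z = _phenotype_latents(cfg, rng, factors)
    pheno = _phenotypes_from_latents(z, rng)
    pheno.index = sample_ids

    # intensities: log-normal with per-metabolite location/scale, run-day factor
    mu = rng.normal(10.0, 1.0, p)
    sigma = rng.uniform(0.3, 0.8, p)
    runday = rng.integers(0, cfg.n_rundays, n)
    if cfg.per_metabolite_runday:
        day_log = rng.normal(0, cfg.runday_scale, (cfg.n_rundays, p))
        batch = day_log[runday, :]
    else:
        day_log = rng.normal(0, cfg.runday_scale, cfg.n_rundays)
        batch = day_log[runday][:, None]
    intens = np.exp(mu[None, :] + sigma[None, :] * latent + batch)

    mask = rng.random((n, p)) < cfg.missing_rate
    intens[mask] = np.nan

    values = pd.DataFrame(intens, index=sample_ids, columns=met_ids)
    runday_s = pd.Series([f"D{d:02d}" for d in runday], index=sample_ids, name="runday")
    abundance = AbundanceMatrix(values, runday_s, stage="raw")

    snp_info = pd.DataFrame(
        {
            "chrom": [str(1 + k % 22) for k in range(cfg.n_snps)],
            "pos": [100_000 + 1_000 * k for k in range(cfg.n_snps)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "consequence": "intergenic_variant",
            "nearest_gene": "",
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    dosages = pd.DataFrame(dos, index=sample_ids, columns=snp_ids)
    genotypes = DosageMatrix(dosages, snp_info)

    truth = SyntheticTruth(
        qtls=tuple(
            (met_ids[q.metabolite], snp_ids[q.snp], q.eaf, q.r2) for q in cfg.planted_qtls
        ),
        modules=tuple(
            (tuple(met_ids[m] for m in mod.members), mod.rho, mod.phenotype, mod.effect)
            for mod in cfg.planted_modules
        ),
        outlier_subjects=outliers,
        covariate_assignments=assignments,
        realized_qtl_r2=realized,
        latent=pd.DataFrame(latent, index=sample_ids, columns=met_ids),
        seed=cfg.seed,
    )
    return abundance, genotypes, cov, pheno, truth


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Tabulate every planted effect, one row each."""
    rows = []
    for met, snp, eaf, r2 in truth.qtls:
        rows.append(
            {
                "kind": "qtl",
                "target": met,
                "source": snp,
                "parameter": r2,
                "detail": f"eaf={eaf:g}",
                "realized_r2": truth.realized_qtl_r2.get((met, snp), np.nan),
            }
        )
    for members, rho, pheno, effect in truth.modules:
        rows.append(
            {
                "kind": "module",
                "target": pheno,
                "source": ";".join(members),
                "parameter": effect,
                "detail": f"rho={rho:g}",
                "realized_r2": np.nan,
            }
        )
    for sid in truth.outlier_subjects:
        rows.append(
            {
                "kind": "outlier",
                "target": sid,
                "source": "",
                "parameter": np.nan,
                "detail": "",
                "realized_r2": np.nan,
            }
        )
    cols = ["kind", "target", "source", "parameter", "detail", "realized_r2"]
    return pd.DataFrame(rows, columns=cols)
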
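"""Metabolome-wide QTL scan, recursive conditioning, variance decomposition.

The scan fits, for every (SNP, metabolite) pair, the additive linear
model ``metabolite ~ dosage + covariates (+ ancestry PCs)``.  It is
computed efficiently by residualizing both metabolites and dosages on
the covariate design and testing the residual correlation with
``df = n - 1 - rank(design)`` degrees of freedom — algebraically
identical (Frisch–Waugh–Lovell) to the per-pair full regression, which
serves as the brute-force oracle in the test suite.

Recursive conditioning reduces the significant SNPs for a metabolite to
an independent set: the top SNP is admitted, then each remaining
candidate is refit conditional on all admitted SNPs and the covariates;
the best conditional p is admitted while it beats 0.05 divided by the
number of remaining candidates, and the procedure stops when the best
p is at or above that Bonferroni bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix, DosageMatrix


@dataclass
class MetQTLResult:
    """Scan output: significant pairs plus a capped sub-threshold store."""

    records: pd.DataFrame  # snp, metabolite, beta, se, p, r2, significant
    threshold: float
    n_samples: int
    n_tests: int


@dataclass
class IndependentSet:
    """Ordered independent SNPs for one metabolite, from recursive conditioning."""

    metabolite: str
    snps: list = field(default_factory=list)  # admission order
    conditional_p: list = field(default_factory=list)
    thresholds: list = field(default_factory=list)  # 0.05/remaining at each admission
    dropped_collinear: list = field(default_factory=list)


def maf_filter(g: DosageMatrix, min_maf: float = 0.01) -> DosageMatrix:
    """Keep SNPs with minor allele frequency strictly above ``min_maf``,
    computed from the analysis sample."""
    eaf = g.eaf()
    maf = np.minimum(eaf, 1 - eaf)
    keep = maf > min_maf
    return DosageMatrix(g.dosages.loc[:, keep[keep].index], g.snp_info.loc[keep[keep].index])


def _residualize(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Project out X (with intercept assumed included); return residuals and rank."""
    Q, R = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(R)) > np.abs(R).max() * 1e-12)) if R.size else 0
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef, rank


def metqtl_scan(
    m: AbundanceMatrix,
    g: DosageMatrix,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    keep_top: int = 100,
) -> MetQTLResult:
    """All-pairs additive SNP - metabolite scan.

    Parameters
    ----------
    covariates
        Numeric design columns (clinical covariates dummy-coded, plus
        ancestry PCs); an intercept is added internally.
    alpha
        Family-wise alpha; the significance bar is
        ``alpha / (n_metabolites * n_snps)``.
    keep_top
        Besides significant pairs, the ``keep_top`` smallest-p SNPs per
        metabolite are retained for inspection.
    """
    m.require_stage("transformed")
    common = m.values.index.intersection(g.dosages.index).intersection(covariates.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between abundance, dosage and covariates")
    Y = m.values.loc[common].to_numpy(dtype=float)
    G = g.dosages.loc[common].to_numpy(dtype=float).copy()
    # missing dosages mean-imputed per SNP (scan only)
    col_mean = np.nanmean(G, axis=0)
    nanmask = np.isnan(G)
    if nanmask.any():
        G[nanmask] = np.take(col_mean, np.where(nanmask)[1])
    X = np.column_stack([np.ones(len(common)), covariates.loc[common].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        names = ["const"] + list(covariates.columns)
        bad = []
        for j in range(1, X.shape[1]):
            sub = X[:, [c for c in range(X.shape[1]) if c != j]]
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    n = len(common)
    Yr, rank = _residualize(Y, X)
    mono = G.std(axis=0) == 0
    Gr, _ = _residualize(G, X)
    df = n - 1 - rank
    ynorm = np.sqrt((Yr**2).sum(axis=0))
    gnorm = np.sqrt((Gr**2).sum(axis=0))
    gnorm[mono] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Gr.T @ Yr) / np.outer(gnorm, ynorm)  # SNPs x metabolites
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df)
    # beta and SE on the dosage scale
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (Gr.T @ Yr) / (gnorm**2)[:, None]
        se = np.abs(beta / t)
    n_tests = m.n_metabolites * g.n_snps
    thr = alpha / n_tests
    sig = p < thr
    # keep significant pairs plus the top `keep_top` per metabolite
    keep = sig.copy()
    if keep_top > 0:
        kth = min(keep_top, p.shape[0])
        idx = np.argpartition(np.where(np.isnan(p), np.inf, p), kth - 1, axis=0)[:kth]
        keep[idx, np.arange(p.shape[1])[None, :]] = True
    keep &= ~np.isnan(p)
    si, mi = np.nonzero(keep)
    snp_ids = np.asarray(g.snp_ids)
    met_ids = np.asarray(m.metabolite_ids)
    records = pd.DataFrame(
        {
            "snp": snp_ids[si],
            "metabolite": met_ids[mi],
            "beta": beta[si, mi],
            "se": se[si, mi],
            "p": p[si, mi],
            "r2": r[si, mi] ** 2,
            "significant": sig[si, mi],
        }
    ).sort_values(["metabolite", "p"], kind="mergesort").reset_index(drop=True)
    return MetQTLResult(records=records, threshold=thr, n_samples=n, n_tests=n_tests)


def _conditional_p(y, X_base, cand):
    """p-value, t and beta of `cand` in y ~ cand + X_base (complete case)."""
    X = np.column_stack([cand, X_base])
    n, q = X.shape
    # collinearity with the admitted set renders the candidate untestable
    if np.linalg.matrix_rank(X) < q:
        return np.nan, np.nan, np.nan
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - q
    if dof <= 0:
        return np.nan, np.nan, np.nan
    sigma2 = (resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * XtX_inv[0, 0])
    if se == 0:
        return np.nan, np.nan, np.nan
    t = coef[0] / se
    return float(2 * stats.t.sf(abs(t), dof)), float(t), float(coef[0])


def recursive_conditioning(
    m: AbundanceMatrix,
    g: DosageMatrix,
    covariates: pd.DataFrame,
    metabolite: str,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
) -> IndependentSet:
    """Reduce a metabolite's significant SNPs to independent signals.

    ``candidates`` holds columns ``snp`` and ``p`` (marginal scan
    p-values) for SNPs that passed the genome-wide bar for this
    metabolite.  The top SNP is admitted outright; thereafter each
    remaining candidate is refit conditioning on every admitted SNP and
    the covariates, and the best conditional p is admitted iff it is
    below ``alpha / (number remaining)``.  Ties in p break by
    (chrom, pos, snp id).  Candidates collinear with the admitted set
    (perfect LD) are dropped, not admitted.
    """
    m.require_stage("transformed")
    out = IndependentSet(metabolite=metabolite)
    cand = candidates.copy()
    if cand.empty:
        return out
    info = g.snp_info
    cand["chrom"] = cand["snp"].map(info["chrom"]).astype(str)
    cand["pos"] = cand["snp"].map(info["pos"])
    cand = cand.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")

    common = m.values.index.intersection(g.dosages.index).intersection(covariates.index)
    y_all = m.values.loc[common, metabolite].astype(float)
    G_all = g.dosages.loc[common, list(dict.fromkeys(cand["snp"]))].astype(float)
    C_all = covariates.loc[common].astype(float)
    keep_rows = y_all.notna() & G_all.notna().all(axis=1) & C_all.notna().all(axis=1)
    y = y_all[keep_rows].to_numpy()
    G = G_all[keep_rows]
    C = np.column_stack([np.ones(int(keep_rows.sum())), C_all[keep_rows].to_numpy()])

    top = cand.iloc[0]
    out.snps.append(top["snp"])
    out.conditional_p.append(float(top["p"]))
    out.thresholds.append(float(top["p"]) + 1.0)  # marginal admission, no conditional bar
    remaining = cand.iloc[1:].copy()
    while not remaining.empty:
        X_base = np.column_stack([G[out.snps].to_numpy(), C])
        results = []
        for _, row in remaining.iterrows():
            p_c, _, _ = _conditional_p(y, X_base, G[row["snp"]].to_numpy())
            results.append((row["snp"], p_c, str(row["chrom"]), row["pos"]))
        res = pd.DataFrame(results, columns=["snp", "p", "chrom", "pos"])
        collinear = res["p"].isna()
        if collinear.any():
            out.dropped_collinear.extend(res.loc[collinear, "snp"].tolist())
            res = res[~collinear]
            remaining = remaining[remaining["snp"].isin(res["snp"])]
        if res.empty:
            break
        res = res.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")
        best = res.iloc[0]
        bar = alpha / len(res)
        if best["p"] >= bar:
            break
        out.snps.append(best["snp"])
        out.conditional_p.append(float(best["p"]))
        out.thresholds.append(bar)
        remaining = remaining[remaining["snp"] != best["snp"]]
    return out


@dataclass
class VarianceDecomposition:
    """Nested-model r² decomposition of one metabolite (or module PC)."""

    target: str
    r2_covariates: float
    snp_ids: list
    snp_r2_increments: list  # incremental r², admission order
    r2_total: float

    @property
    def r2_genetic(self) -> float:
        return float(sum(self.snp_r2_increments))

    @property
    def unexplained(self) -> float:
        return float(1.0 - self.r2_total)


def _r2(y: np.ndarray, X: np.ndarray, adjusted: bool = False) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    r2 = 1.0 - (resid @ resid) / tss
    if adjusted:
        n, q = X.shape
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - q)
    return float(r2)


def variance_explained(
    m: AbundanceMatrix,
    g: DosageMatrix,
    covariates: pd.DataFrame,
    independent: IndependentSet,
    adjusted: bool = False,
) -> VarianceDecomposition:
    """Decompose a metabolite's variance into clinical and per-SNP parts.

    ``r2_covariates`` comes from the covariate-only model; SNP
    contributions are incremental r² from nested models that add the
    independent SNPs in admission order (top SNP first), so each
    increment is non-negative and the per-SNP rows sum to the genetic
    share.
    """
    m.require_stage("transformed")
    met = independent.metabolite
    if met not in m.values.columns:
        raise ValueError(f"metabolite {met!r} not in abundance matrix")
    common = m.values.index.intersection(g.dosages.index).intersection(covariates.index)
    y = m.values.loc[common, met].astype(float)
    snp_cols = g.dosages.loc[common, independent.snps] if independent.snps else None
    C = covariates.loc[common].astype(float)
    keep = y.notna() & C.notna().all(axis=1)
    if snp_cols is not None:
        keep &= snp_cols.notna().all(axis=1)
    yv = y[keep].to_numpy()
    if yv.size == 0:
        raise ValueError("empty metabolite profile after complete-case filtering")
    X = np.column_stack([np.ones(int(keep.sum())), C[keep].to_numpy()])
    r2_cov = _r2(yv, X, adjusted)
    increments = []
    prev = r2_cov
    for snp in independent.snps:
        X = np.column_stack([X, snp_cols.loc[keep, snp].to_numpy()])
        cur = _r2(yv, X, adjusted)
        increments.append(max(cur - prev, 0.0))
        prev = cur
    return VarianceDecomposition(
        target=met,
        r2_covariates=r2_cov,
        snp_ids=list(independent.snps),
        snp_r2_increments=increments,
        r2_total=prev,
    )


def condition_all(
    m: AbundanceMatrix,
    g: DosageMatrix,
    covariates: pd.DataFrame,
    scan: MetQTLResult,
    alpha: float = 0.05,
) -> dict[str, IndependentSet]:
    """Run recursive conditioning for every metabolite with significant SNPs."""
    sig = scan.records[scan.records["significant"]]
    out = {}
    for met, grp in sig.groupby("metabolite", sort=True):
        out[met] = recursive_conditioning(
            m, g, covariates, met, grp[["snp", "p"]], alpha=alpha
        )
    return out
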
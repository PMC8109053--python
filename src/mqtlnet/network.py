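"""Gaussian graphical model of metabolite co-abundance and
phenotype-driven module discovery.

The GGM estimates full-order partial correlations — the correlation
between two metabolites conditioning on all other metabolites and the
clinical confounders.  With hundreds of metabolites and comparable
sample sizes the sample correlation matrix is (near-)singular, so a
Schäfer–Strimmer analytic shrinkage toward the identity is applied
before inversion; the estimated shrinkage intensity is recorded in the
network metadata.  Edges require a Bonferroni-significant, positive
partial correlation above ``pcor_min``; negative partial correlations
are never edged (they are treated as spurious).

Module discovery is a greedy seed-and-expand search: every metabolite
node seeds a candidate module whose representative profile is the mean
of its members' transformed intensities; neighbors join only while the
extended module scores higher (on -log10 p against the residualized
phenotype) than the current module and than every single member.
Overlapping seed-optimal modules are merged under the same rule, and
module p-values are Bonferroni-adjusted over the number of seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def shrinkage_correlation(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Schäfer–Strimmer shrinkage of the sample correlation toward identity.

    The analytic intensity is the ratio of the summed estimated
    variances of the off-diagonal correlations to their summed squares,
    clipped to [0, 1].
    """
    n, p = X.shape
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Xs.T @ Xs) / (n - 1)
    # var_hat(r_ij) via the standardized cross-products w_kij = x_ki x_kj
    W2 = (Xs**2).T @ (Xs**2)  # sum_k w_kij^2
    sum_w = R * (n - 1)
    var_r = n / (n - 1) ** 3 * (W2 - sum_w**2 / n)
    off = ~np.eye(p, dtype=bool)
    denom = (R[off] ** 2).sum()
    lam = 1.0 if denom == 0 else float(np.clip(var_r[off].sum() / denom, 0.0, 1.0))
    R_star = (1 - lam) * R
    np.fill_diagonal(R_star, 1.0)
    return R_star, lam


def partial_correlations(R: np.ndarray) -> np.ndarray:
    """Full-order partial correlation matrix from a (regularized) correlation."""
    P = np.linalg.inv(R)
    d = np.sqrt(np.diag(P))
    pcor = -P / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def residualize_on(design: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Residualize every column of Y on a covariate table (plus intercept)."""
    parts = [pd.Series(1.0, index=design.index, name="const")]
    for c in design.columns:
        col = design[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float))
    X = pd.concat(parts, axis=1).to_numpy(dtype=float)
    Ym = Y.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Ym, rcond=None)
    return pd.DataFrame(Ym - X @ coef, index=Y.index, columns=Y.columns)


def estimate_ggm(
    m,
    confounders: pd.DataFrame | None = None,
    alpha: float = 0.05,
    pcor_min: float = 0.2,
    denominator: int | None = None,
    pairwise_denominator: bool = False,
) -> nx.Graph:
    """Estimate the metabolite partial-correlation network.

    Edge rule: partial correlation > ``pcor_min`` AND Fisher-z p-value
    below ``alpha`` / denominator, where the denominator defaults to
    (number of metabolites)² (the printed test count convention), or
    p(p-1)/2 with ``pairwise_denominator=True``.  Negative partial
    correlations never form edges.
    """
    m.require_stage("transformed")
    n, p = m.values.shape
    if confounders is not None:
        n_conf = sum(
            confounders[c].nunique() if confounders[c].dtype == object else 1
            for c in confounders.columns
        )
        if n <= n_conf:
            raise ValueError("fewer samples than confounder columns")
        Y = residualize_on(confounders.loc[m.values.index], m.values)
    else:
        Y = m.values
    if n < 30:
        raise ValueError("GGM estimation needs at least 30 subjects")
    R_star, lam = shrinkage_correlation(Y.to_numpy(dtype=float))
    if lam >= 1.0:
        warnings.warn("shrinkage intensity reached 1 (pure diagonal)", RuntimeWarning,
                      stacklevel=2)
    pcor = partial_correlations(R_star)
    # Fisher z with effective df n - 3 (shrinkage invalidates the classical
    # conditioning-count correction; documented approximation)
    z = np.arctanh(np.clip(pcor, -1 + 1e-15, 1 - 1e-15))
    pvals = 2 * stats.norm.sf(np.abs(z) * np.sqrt(max(n - 3, 1)))
    denom = denominator if denominator is not None else (p * (p - 1) // 2 if pairwise_denominator else p * p)
    bar = alpha / denom
    G = nx.Graph(
        shrinkage_intensity=lam, n_samples=n, bonferroni_denominator=denom,
        alpha=alpha, pcor_min=pcor_min,
    )
    mets = list(m.values.columns)
    G.add_nodes_from(mets, kind="metabolite")
    iu = np.triu_indices(p, k=1)
    for i, j in zip(*iu):
        pc = pcor[i, j]
        if pc > pcor_min and pvals[i, j] < bar:
            G.add_edge(mets[i], mets[j], pcor=float(pc), p=float(pvals[i, j]),
                       provenance="ggm")
    return G


def add_snp_nodes(G: nx.Graph, independent_sets: dict) -> nx.Graph:
    """Attach SNP nodes and met-QTL edges to a metabolite network.

    One SNP node per independent met-QTL SNP; an edge per admitted
    (SNP, metabolite) association.  Metabolite-metabolite edges are
    untouched.  Independent sets whose metabolite was filtered out
    upstream are skipped with a warning.
    """
    G = G.copy()
    for met, ind in independent_sets.items():
        if met not in G:
            warnings.warn(
                f"metabolite {met!r} has met-QTLs but is absent from the network; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        for snp, p in zip(ind.snps, ind.conditional_p):
            if snp not in G:
                G.add_node(snp, kind="snp")
            G.add_edge(snp, met, p=float(p), provenance="metqtl")
    return G


def network_summary(G: nx.Graph) -> tuple[int, int, int]:
    """(metabolite nodes, SNP nodes, edges)."""
    kinds = nx.get_node_attributes(G, "kind")
    n_met = sum(1 for v in kinds.values() if v == "metabolite")
    n_snp = sum(1 for v in kinds.values() if v == "snp")
    return n_met, n_snp, G.number_of_edges()


def residualize_phenotype(
    phenotype: pd.Series, covariates: pd.DataFrame
) -> pd.Series:
    """Residualize a phenotype on its covariate set (complete case)."""
    keep = phenotype.notna() & covariates.notna().all(axis=1)
    resid = residualize_on(
        covariates.loc[keep], phenotype.loc[keep].astype(float).to_frame("y")
    )["y"]
    return resid


def score_profile(profile: np.ndarray, pheno_resid: np.ndarray) -> tuple[float, float]:
    """Score a (module or metabolite) profile against a residualized phenotype.

    Simple linear model ``profile ~ pheno_resid``; returns the phenotype
    coefficient and -log10 of its two-sided p-value.  A zero-variance
    profile scores 0.
    """
    y = np.asarray(profile, dtype=float)
    x = np.asarray(pheno_resid, dtype=float)
    if y.size != x.size:
        raise ValueError("profile and residualized phenotype lengths differ")
    if y.std() == 0 or x.std() == 0:
        return 0.0, 0.0
    n = y.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = (xc**2).sum()
    beta = float((xc @ yc) / sxx)
    resid = yc - beta * xc
    dof = n - 2
    sigma2 = (resid @ resid) / dof
    se = np.sqrt(sigma2 / sxx)
    if se == 0:  # perfectly collinear profile; p underflows to the machine floor
        return beta, float(-np.log10(np.nextafter(0, 1)))
    t = beta / se
    logp = np.log(2.0) + stats.t.logsf(abs(t), dof)  # stays finite far past float p
    return beta, float(-logp / np.log(10.0))


@dataclass
class ModuleVarianceDecomposition:
    """Genetic vs clinical r² for a module's first principal component."""

    module_seed: str
    phenotype: str
    snp_ids: list
    r2_genetic: float
    r2_covariates: float


@dataclass
class PhenotypeModule:
    """A connected metabolite set scored against one phenotype."""

    phenotype: str
    members: tuple
    seed: str
    beta: float
    score: float  # -log10 raw p
    adjusted_p: float
    adjusted_score: float
    merge_history: tuple = ()

    @property
    def size(self) -> int:
        return len(self.members)


def _module_profile(values: pd.DataFrame, members) -> np.ndarray:
    return values[list(members)].to_numpy(dtype=float).mean(axis=1)


def greedy_module_search(
    G: nx.Graph,
    m,
    pheno_resid: pd.Series,
    phenotype: str = "phenotype",
    alpha: float = 0.05,
) -> list[PhenotypeModule]:
    """Phenotype-driven greedy module identification on a GGM.

    Every metabolite node seeds one search.  At each step the best
    neighbor (by the score of the extended module, ties broken by
    metabolite id) joins iff the extended score strictly exceeds both
    the current module score and the score of every individual member
    of the extended module.  Overlapping seed-optimal modules are then
    merged (union) when the merged module passes the same rule,
    otherwise the higher-scoring one is kept.  Module p-values are
    Bonferroni-corrected over the number of seeds; only modules with
    adjusted p < ``alpha`` are returned.
    """
    m.require_stage("transformed")
    common = m.values.index.intersection(pheno_resid.index)
    vals = m.values.loc[common]
    x = pheno_resid.loc[common].to_numpy(dtype=float)
    mets = [v for v, d in G.nodes(data=True) if d.get("kind", "metabolite") == "metabolite"]
    mets = [v for v in mets if v in vals.columns]
    if not mets:
        return []
    single_score = {}
    single_beta = {}
    for v in mets:
        b, s = score_profile(vals[v].to_numpy(dtype=float), x)
        single_beta[v] = b
        single_score[v] = s

    def module_score(members) -> tuple[float, float]:
        return score_profile(_module_profile(vals, members), x)

    met_set = set(mets)
    optimal = {}
    for seed in sorted(mets):
        members = [seed]
        beta, score = single_beta[seed], single_score[seed]
        while True:
            neigh = set()
            for v in members:
                neigh.update(w for w in G.neighbors(v)
                             if w in met_set and w not in members)
            best = None
            for w in sorted(neigh):
                cand = members + [w]
                b, s = module_score(cand)
                if not np.isfinite(s):
                    continue
                # admissible: beats the current module and every single member
                if s <= score or any(s <= single_score[v] for v in cand):
                    continue
                if best is None or s > best[1]:
                    best = (w, s, b)
            if best is None:
                break
            w, s, b = best
            members.append(w)
            score, beta = s, b
        optimal[seed] = (frozenset(members), beta, score)

    # deduplicate identical member sets, then merge overlapping modules
    modules = {}
    for seed in sorted(optimal):
        members, beta, score = optimal[seed]
        if members not in modules or score > modules[members][1]:
            modules[members] = (seed, beta, score, (seed,))
    merged = True
    while merged:
        merged = False
        keys = sorted(modules, key=lambda k: (-modules[k][2], sorted(k)[0]))
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b_ = keys[i], keys[j]
                if a in modules and b_ in modules and a & b_:
                    union = a | b_
                    beta_u, score_u = module_score(union)
                    if score_u > max(modules[a][2], modules[b_][2]) and all(
                        score_u > single_score[v] for v in union
                    ):
                        seed_a, _, _, hist_a = modules[a]
                        _, _, _, hist_b = modules[b_]
                        del modules[a], modules[b_]
                        modules[frozenset(union)] = (
                            seed_a, beta_u, score_u, tuple(hist_a) + tuple(hist_b)
                        )
                    else:
                        drop = a if modules[a][2] < modules[b_][2] else b_
                        del modules[drop]
                    merged = True
                    break
            if merged:
                break

    n_seeds = len(mets)
    out = []
    for members, (seed, beta, score, hist) in modules.items():
        raw_p = 10.0 ** (-score)
        adj_p = min(raw_p * n_seeds, 1.0)
        if adj_p < alpha:
            out.append(
                PhenotypeModule(
                    phenotype=phenotype,
                    members=tuple(sorted(members)),
                    seed=seed,
                    beta=beta,
                    score=score,
                    adjusted_p=adj_p,
                    adjusted_score=float(-np.log10(adj_p)) if adj_p > 0 else score,
                    merge_history=hist,
                )
            )
    out.sort(key=lambda mod: (-mod.score, mod.members))
    for mod in out:  # admission-rule invariant, asserted on output
        assert all(mod.score >= single_score[v] for v in mod.members)
    return out


def module_variance_decomposition(
    module: PhenotypeModule,
    m,
    g,
    independent_sets: dict,
    covariates: pd.DataFrame,
    adjusted: bool = False,
) -> ModuleVarianceDecomposition:
    """Variance of a module's first principal component explained by its
    members' independent met-QTL SNPs vs by the clinical covariates.

    The PC is computed from the members' transformed intensities
    (columns standardized), oriented so the mean loading is >= 0.
    """
    from .qtl import _r2

    m.require_stage("transformed")
    if module.size < 2:
        raise ValueError("module variance decomposition needs >= 2 members")
    common = m.values.index.intersection(covariates.index).intersection(g.dosages.index)
    Y = m.values.loc[common, list(module.members)].to_numpy(dtype=float)
    Ys = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    _, _, Vt = np.linalg.svd(Ys, full_matrices=False)
    load = Vt[0]
    if load.mean() < 0:
        load = -load
    pc = Ys @ load
    snps = []
    for met in module.members:
        ind = independent_sets.get(met)
        if ind is not None:
            snps.extend(s for s in ind.snps if s not in snps)
    Xc_parts = [pd.Series(1.0, index=common, name="const")]
    for c in covariates.columns:
        col = covariates.loc[common, c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            Xc_parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            Xc_parts.append(col.astype(float))
    Xc = pd.concat(Xc_parts, axis=1).to_numpy(dtype=float)
    r2_cov = _r2(pc, Xc, adjusted)
    if snps:
        Xg = np.column_stack(
            [np.ones(len(common)), g.dosages.loc[common, snps].to_numpy(dtype=float)]
        )
        r2_gen = _r2(pc, Xg, adjusted)
    else:
        r2_gen = 0.0
    return ModuleVarianceDecomposition(
        module_seed=module.seed,
        phenotype=module.phenotype,
        snp_ids=snps,
        r2_genetic=float(r2_gen),
        r2_covariates=float(r2_cov),
    )
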
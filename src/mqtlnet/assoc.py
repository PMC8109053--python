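"""Phenotype-metabolite association testing.

Five COPD phenotypes are tested per metabolite with phenotype-matched
model families: linear models for FEV1 percent predicted, FEV1/FVC and
percent emphysema (metabolite as response), logistic regression for
chronic bronchitis and negative-binomial regression for exacerbation
counts (phenotype as response, metabolite as exposure).  Significance
is Bonferroni within phenotype over the number of metabolites tested.
Also provides the univariate demographic screen and the cohort-table
group tests (chi-square for binary traits, one-way ANOVA reconstructed
from per-group summary statistics for continuous traits).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import AbundanceMatrix, AssociationRecord

#: phenotype -> default model family
DEFAULT_FAMILIES = {
    "fev1pp": "linear",
    "fev1_fvc": "linear",
    "pct_emphysema": "linear",
    "chronic_bronchitis": "logistic",
    "exacerbation_count": "negbin",
}

DEFAULT_COVARIATES = ["age", "sex", "bmi", "current_smoker", "pack_years", "center"]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def build_design(cov: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Covariate design matrix with intercept; categoricals dummy-coded."""
    columns = columns if columns is not None else [c for c in DEFAULT_COVARIATES if c in cov]
    parts = [pd.Series(1.0, index=cov.index, name="const")]
    for c in columns:
        col = cov[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _fit_one(y, X, family: str, coef: str):
    """Fit one model, return (beta, se, p, converged) for the named column."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "linear":
                res = sm.OLS(y, X).fit()
                ok = True
            elif family == "logistic":
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                ok = bool(res.mle_retvals.get("converged", True))
            elif family == "negbin":
                try:
                    res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
                    ok = bool(res.mle_retvals.get("converged", True))
                    if not np.isfinite(res.bse[coef]):
                        ok = False
                except Exception:
                    ok = False
                if not ok:  # Poisson fallback when the NB fit degenerates
                    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                    ok = True
            elif family == "poisson":
                res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
                ok = True
            else:
                raise ValueError(f"unknown model family {family!r}")
        except Exception:
            return np.nan, np.nan, np.nan, False
    beta = float(res.params[coef])
    se = float(res.bse[coef])
    p = float(res.pvalues[coef])
    if not np.isfinite(p):
        return beta, se, np.nan, False
    return beta, se, p, ok


def fit_metabolite_phenotype(
    m: AbundanceMatrix,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype: str,
    family: str | None = None,
    covariate_columns: list[str] | None = None,
    alpha: float = 0.05,
    metabolite_as_response: bool = True,
) -> list[AssociationRecord]:
    """Test every metabolite against one phenotype, with covariates.

    For continuous phenotypes the default model is
    ``metabolite ~ phenotype + covariates`` and the reported beta is the
    phenotype coefficient; for binary/count phenotypes the phenotype is
    the response and the metabolite coefficient is reported.  Rows with
    any missing value among phenotype, covariates or metabolite are
    dropped (complete case).  Non-converged fits yield a record with
    ``converged=False`` and missing p, never a silently dropped row.
    """
    m.require_stage("transformed")
    family = family or DEFAULT_FAMILIES.get(phenotype, "linear")
    common = m.values.index.intersection(phenotypes.index).intersection(covariates.index)
    y_pheno = phenotypes.loc[common, phenotype].astype(float)
    X_cov = build_design(covariates.loc[common], covariate_columns)
    thr = bonferroni_threshold(alpha, m.n_metabolites)
    records = []
    for met in m.metabolite_ids:
        met_vals = m.values.loc[common, met].astype(float)
        keep = met_vals.notna() & y_pheno.notna() & X_cov.notna().all(axis=1)
        n_used = int(keep.sum())
        if family == "linear" and metabolite_as_response:
            X = X_cov.loc[keep].copy()
            X.insert(1, "phenotype", y_pheno.loc[keep])
            beta, se, p, ok = _fit_one(met_vals.loc[keep], X, family, "phenotype")
        else:
            X = X_cov.loc[keep].copy()
            X.insert(1, "metabolite", met_vals.loc[keep])
            beta, se, p, ok = _fit_one(y_pheno.loc[keep], X, family, "metabolite")
        records.append(
            AssociationRecord(
                metabolite=met,
                phenotype=phenotype,
                family=family,
                beta=beta,
                se=se,
                p=p,
                significant=bool(np.isfinite(p) and p < thr),
                n=n_used,
                converged=ok,
            )
        )
    return records


def demographic_screen(
    m: AbundanceMatrix, demographics: pd.DataFrame, alpha: float = 0.05
) -> list[AssociationRecord]:
    """Univariate linear regressions of each metabolite on each demographic.

    One record per (metabolite, variable); significance Bonferroni over
    metabolites within each variable.  Constant variables are skipped
    with a warning.
    """
    m.require_stage("transformed")
    common = m.values.index.intersection(demographics.index)
    thr = bonferroni_threshold(alpha, m.n_metabolites)
    Y = m.values.loc[common].to_numpy(dtype=float)
    n = len(common)
    records = []
    for var in demographics.columns:
        col = demographics.loc[common, var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            col = pd.get_dummies(col, drop_first=True, dtype=float)
            if col.shape[1] == 0:
                warnings.warn(f"constant demographic {var!r} skipped", RuntimeWarning,
                              stacklevel=2)
                continue
            col = col.iloc[:, 0]  # first contrast for the univariate screen
        x = col.to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0:
            warnings.warn(f"constant demographic {var!r} skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        # vectorized simple regression of every metabolite on this variable
        ok = np.isfinite(x)
        xs = x[ok] - x[ok].mean()
        Yok = Y[ok]
        Yc = Yok - Yok.mean(axis=0)
        sxx = (xs**2).sum()
        beta = (xs @ Yc) / sxx
        resid = Yc - np.outer(xs, beta)
        dof = ok.sum() - 2
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = beta / se
        p = 2 * stats.t.sf(np.abs(t), dof)
        for j, met in enumerate(m.metabolite_ids):
            records.append(
                AssociationRecord(
                    metabolite=met,
                    phenotype=var,
                    family="linear",
                    beta=float(beta[j]),
                    se=float(se[j]),
                    p=float(p[j]),
                    significant=bool(p[j] < thr),
                    n=int(ok.sum()),
                )
            )
    return records


def chi_square_group_test(counts: pd.DataFrame | np.ndarray) -> float:
    """Pearson chi-square p for a groups x {yes, no} count table.

    ``counts`` rows are groups, columns are (events, non-events).  No
    continuity correction, matching the convention for cohort tables.
    """
    table = np.asarray(counts, dtype=float)
    if table.shape[0] < 2:
        raise ValueError("need at least two groups")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


def anova_from_summaries(n: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA F and p reconstructed exactly from per-group n/mean/SD."""
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if n.size < 2:
        raise ValueError("need at least two groups")
    if (n < 2).any():
        raise ValueError("each group needs n >= 2 for ANOVA from summaries")
    N = n.sum()
    k = n.size
    grand = (n * mean).sum() / N
    ss_between = (n * (mean - grand) ** 2).sum()
    ss_within = ((n - 1) * sd**2).sum()
    f = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(stats.f.sf(f, k - 1, N - k))
    return float(f), p


def cohort_table_tests(summary: pd.DataFrame) -> pd.DataFrame:
    """Group-difference tests for a cohort characteristics table.

    ``summary`` has one row per (trait, group) with columns ``trait``,
    ``group``, ``n`` and either ``count`` (binary traits) or
    ``mean``/``sd`` (continuous traits).  Binary traits get a Pearson
    chi-square test of independence; continuous traits a one-way ANOVA
    from summaries.  Returns one row per trait with the test used and p.
    """
    out = []
    for trait, grp in summary.groupby("trait", sort=False):
        if grp["group"].nunique() < 2:
            raise ValueError(f"trait {trait!r} has fewer than two groups")
        if "count" in grp.columns and grp["count"].notna().all():
            counts = np.column_stack(
                [grp["count"].to_numpy(float), (grp["n"] - grp["count"]).to_numpy(float)]
            )
            p = chi_square_group_test(counts)
            out.append({"trait": trait, "test": "chi_square", "p": p})
        else:
            _, p = anova_from_summaries(
                grp["n"].to_numpy(), grp["mean"].to_numpy(), grp["sd"].to_numpy()
            )
            out.append({"trait": trait, "test": "anova", "p": p})
    return pd.DataFrame(out)
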
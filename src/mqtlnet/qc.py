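"""Pre-analysis chain for batch-structured metabolite intensities.

Order is enforced: run-day normalization -> missingness filter -> kNN
imputation -> subject outlier removal -> rank-based inverse normal
transform.  Each step returns a new :class:`AbundanceMatrix` at the next
stage; calling a step out of order raises :class:`StageError`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .containers import AbundanceMatrix, QCReport


def runday_normalize(m: AbundanceMatrix, report: QCReport | None = None) -> AbundanceMatrix:
    """Divide each intensity by its metabolite's run-day median and
    multiply by the metabolite's overall median.

    Corrects multiplicative shifts from instrument inter-day tuning
    differences.  Medians use non-missing cells only; a metabolite whose
    cells are entirely missing on some run day is left missing there and
    flagged in the report.
    """
    m.require_stage("raw")
    report = report if report is not None else QCReport()
    vals = m.values.to_numpy(dtype=float).copy()
    days = m.runday.to_numpy()
    out = vals.copy()
    day_labels = pd.unique(days)
    overall = np.nanmedian(np.where(np.isnan(vals), np.nan, vals), axis=0)
    pre_med, post_med = {}, {}
    for d in day_labels:
        rows = days == d
        block = vals[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN day blocks
            day_med = np.nanmedian(block, axis=0)
        pre_med[d] = float(np.nanmedian(block))
        empty = np.isnan(day_med)
        if empty.any():
            for j in np.flatnonzero(empty):
                report.log(
                    f"metabolite {m.values.columns[j]} entirely missing on run day {d}"
                )
        zero = day_med == 0
        if zero.any():
            j = int(np.flatnonzero(zero)[0])
            raise ValueError(
                f"zero run-day median for metabolite {m.values.columns[j]} on day {d}"
            )
        factor = np.where(empty, np.nan, overall / day_med)
        out[rows] = block * factor[None, :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            post_med[d] = float(np.nanmedian(out[rows]))
    report.runday_shift = pd.DataFrame(
        {
            "runday": list(day_labels),
            "pre_median": [pre_med[d] for d in day_labels],
            "post_median": [post_med[d] for d in day_labels],
        }
    )
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advance(values, "normalized")


def filter_missingness(
    m: AbundanceMatrix, max_missing: float = 0.20
) -> tuple[AbundanceMatrix, QCReport]:
    """Drop metabolites missing in strictly more than ``max_missing`` of samples."""
    m.require_stage("normalized")
    frac = m.values.isna().mean(axis=0)
    drop = frac > max_missing
    report = QCReport()
    report.removed_metabolites = pd.DataFrame(
        {"metabolite": frac.index[drop], "missing_fraction": frac[drop].to_numpy()}
    ).reset_index(drop=True)
    kept = m.values.loc[:, ~drop]
    if kept.shape[1] == 0:
        raise ValueError(
            f"all {m.n_metabolites} metabolites exceed the {max_missing:.0%} "
            "missingness limit; nothing left to analyze"
        )
    return m.advance(kept, "filtered"), report


def _pairwise_distances(vals: np.ndarray) -> np.ndarray:
    """Metabolite-metabolite Euclidean distances over shared observed samples,
    scaled by the number of shared samples (root mean squared difference)."""
    obs = (~np.isnan(vals)).astype(float)
    x = np.where(np.isnan(vals), 0.0, vals)
    x2 = x**2
    # sum over shared samples of (xi - xj)^2, via masked cross-products
    ss = x2.T @ obs + obs.T @ x2 - 2.0 * (x.T @ x)
    shared = obs.T @ obs
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = ss / shared
    d2[shared == 0] = np.inf
    np.fill_diagonal(d2, np.inf)
    return np.sqrt(np.clip(d2, 0.0, None))


def knn_impute(
    m: AbundanceMatrix, k: int = 10, report: QCReport | None = None
) -> AbundanceMatrix:
    """Impute missing cells from the k nearest metabolites.

    Neighbors are metabolites; the distance between two metabolites is
    the root-mean-square intensity difference over samples where both
    are observed.  A missing cell (sample i, metabolite j) is replaced
    by the mean of j's k nearest metabolites' values at sample i
    (neighbors themselves missing at i are skipped); if no neighbor is
    observed at i, the metabolite's own mean is used and the fallback
    is logged.
    """
    m.require_stage("filtered")
    if m.n_metabolites < k + 1:
        raise ValueError(f"kNN imputation with k={k} needs at least {k + 1} metabolites")
    report = report if report is not None else QCReport()
    vals = m.values.to_numpy(dtype=float).copy()
    if not np.isnan(vals).any():
        return m.advance(m.values.copy(), "imputed")
    dist = _pairwise_distances(vals)
    col_means = np.nanmean(vals, axis=0)
    out = vals.copy()
    for j in range(vals.shape[1]):
        miss_rows = np.flatnonzero(np.isnan(vals[:, j]))
        if miss_rows.size == 0:
            continue
        order = np.argsort(dist[j])
        neighbors = order[np.isfinite(dist[j][order])][:k]
        nb_vals = vals[np.ix_(miss_rows, neighbors)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fill = np.nanmean(nb_vals, axis=1)
        no_nb = np.isnan(fill)
        if no_nb.any():
            fill[no_nb] = col_means[j]
            for i in miss_rows[no_nb]:
                report.log(
                    f"no observed neighbor for ({m.values.index[i]}, "
                    f"{m.values.columns[j]}); column mean used"
                )
        out[miss_rows, j] = fill
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advance(values, "imputed")


def remove_outlier_subjects(
    m: AbundanceMatrix, z_cut: float = 3.5, two_sided: bool = True
) -> tuple[AbundanceMatrix, QCReport]:
    """Remove subjects whose aggregate metabolite median z-score is extreme.

    Per metabolite, intensities are z-scored across subjects; each
    subject's median z over metabolites is then standardized across
    subjects, and subjects beyond ``z_cut`` standard deviations from the
    mean are removed (two-sided by default; ``two_sided=False``
    reproduces a high-side-only rule).
    """
    m.require_stage("imputed")
    report = QCReport()
    n = m.n_samples
    if n < 3:
        report.log("fewer than 3 subjects; outlier standardization degenerate, none removed")
        return m.advance(m.values.copy(), "imputed"), report
    vals = m.values.to_numpy(dtype=float)
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance metabolites; z-scores set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - vals.mean(axis=0)) / sd
    z[:, zero_var] = 0.0
    med = np.median(z, axis=1)
    med_sd = med.std(ddof=1)
    if med_sd == 0:
        return m.advance(m.values.copy(), "imputed"), report
    std_med = (med - med.mean()) / med_sd
    flag = np.abs(std_med) > z_cut if two_sided else std_med > z_cut
    report.removed_subjects = pd.DataFrame(
        {"sample": m.values.index[flag], "median_z": std_med[flag]}
    ).reset_index(drop=True)
    kept = m.values.loc[~flag]
    return m.advance(kept, "imputed"), report


def inverse_normal_transform(m: AbundanceMatrix, offset: float = 3.0 / 8.0) -> AbundanceMatrix:
    """Rank-based inverse normal (normal quantile) transform, per metabolite.

    Values are mapped to Phi^{-1}((rank - c) / (n - 2c + 1)) with the
    Blom offset c = 3/8 by default; ties get average ranks.  Constant
    columns come out all zero with a warning.
    """
    m.require_stage("imputed")
    if m.values.isna().any().any():
        raise ValueError("missing cells remain; impute before transforming")
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[0]
    out = np.empty_like(vals)
    denom = n - 2 * offset + 1
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"constant metabolite {m.values.columns[j]}; transformed to zeros",
                RuntimeWarning,
                stacklevel=2,
            )
            out[:, j] = 0.0
            continue
        ranks = stats.rankdata(col, method="average")
        out[:, j] = ndtri((ranks - offset) / denom)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.advance(values, "transformed")


def preprocess(
    m: AbundanceMatrix,
    max_missing: float = 0.20,
    k: int = 10,
    z_cut: float = 3.5,
) -> tuple[AbundanceMatrix, QCReport]:
    """Run the full pre-analysis chain, merging the per-step reports."""
    report = QCReport()
    m = runday_normalize(m, report)
    m, rep_f = filter_missingness(m, max_missing)
    report.removed_metabolites = rep_f.removed_metabolites
    m = knn_impute(m, min(k, m.n_metabolites - 1), report)
    m, rep_o = remove_outlier_subjects(m, z_cut)
    report.removed_subjects = rep_o.removed_subjects
    report.notes.extend(rep_o.notes)
    m = inverse_normal_transform(m)
    return m, report
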
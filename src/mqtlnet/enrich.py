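"""Annotation-group enrichment of significant features.

One-tailed (over-representation) Fisher's exact test of significant
features within each annotation group — metabolite subpathways, super
pathways, or SNP consequence classes — against the full tested feature
set, with Benjamini–Hochberg adjustment across groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    hits: set, universe: set, grouping: dict, min_group_size: int = 2
) -> pd.DataFrame:
    """Per-group over-representation of ``hits`` within ``universe``.

    Every universe id maps to a group via ``grouping`` (unmapped ids go
    to "unannotated").  For each group the 2x2 table
    (in-group/out-group x hit/non-hit) gets an upper-tail Fisher exact
    p; groups smaller than ``min_group_size`` are reported but flagged
    underpowered.  Rows sorted by p, with BH q across groups.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hits)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    groups: dict = {}
    for fid in universe:
        groups.setdefault(grouping.get(fid, "unannotated"), set()).add(fid)
    n_hits = len(hits)
    N = len(universe)
    rows = []
    for label in sorted(groups):
        members = groups[label]
        a = len(hits & members)
        b = n_hits - a
        c = len(members) - a
        d = N - len(members) - b
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "group": label,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": odds,
                "p": float(p),
                "underpowered": len(members) < min_group_size,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < 0.05
    return df.sort_values(["p", "group"], kind="mergesort").reset_index(drop=True)
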
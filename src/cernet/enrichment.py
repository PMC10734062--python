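"""Over-representation analysis of gene sets (hypergeometric, one-sided).

The universe is the set of genes measurable on the platform (not the
genome), which keeps the sampling frame honest for array data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UserError
from .io import GeneSetCollection


def hypergeometric_ora(query, annotated, universe_size: int) -> float:
    """Upper-tail P(X >= |query ∩ annotated|) under random draws.

    ``query`` and ``annotated`` are gene collections drawn from a universe of
    ``universe_size`` genes.
    """
    query, annotated = set(query), set(annotated)
    overlap = len(query & annotated)
    if len(query) > universe_size or len(annotated) > universe_size:
        raise UserError("set larger than the universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, len(annotated), len(query)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise UserError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """ORA of one query gene list against every set in a collection.

    Sets and the query are restricted to the universe first; rows are
    BH-adjusted across the collection and sorted by P (name-stable ties).
    """
    universe = set(universe)
    if not universe:
        raise UserError("empty universe")
    query = set(query) & universe
    rows = []
    for name in collection.names():
        members = set(collection.sets[name]) & universe
        overlap = query & members
        p = hypergeometric_ora(query, members, len(universe)) if members else 1.0
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "query_size": len(query),
                "overlap": len(overlap),
                "overlap_genes": ";".join(sorted(overlap)),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "query_size", "overlap", "overlap_genes", "p_value"],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"])
        df = df.sort_values(["p_value", "set_name"], ignore_index=True)
    else:
        df["q_value"] = []
    return df
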
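"""DE lnc/circRNA - mRNA co-expression networks.

For each contrast, every (DE sponge, DE mRNA) pair is scored by Pearson
correlation of log2 expression across the contrast's samples; pairs with
r > 0.2 (signed: ceRNA logic expects positive coupling) and two-tailed
P < 0.05 are retained as network edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UserError
from .io import ExpressionMatrix


@dataclass(frozen=True)
class CoexpressionEdge:
    """One retained sponge-mRNA correlation in one contrast."""

    sponge_feature_id: str
    mrna_feature_id: str
    pcc: float
    p_value: float
    contrast: str
    n_samples: int


def pcc(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UserError("pcc expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise UserError("pcc needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UserError("pcc is undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def pcc_pvalue(r: float, n: int) -> float:
    """Two-tailed P for a correlation r over n observations.

    Uses the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df. For
    |r| = 1 the statistic is infinite; the smallest representable P is
    returned with a warning.
    """
    if n < 3:
        raise UserError("pcc p-value needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise UserError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: returning smallest representable p", stacklevel=2)
        return float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_pairs(
    m: ExpressionMatrix, sponges, mrnas, samples
) -> pd.DataFrame:
    """All sponge x mRNA Pearson correlations and P values (vectorized).

    Returns a long-form DataFrame (sponge, mrna, pcc, p_value) over every
    pair, unthresholded.
    """
    sponges, mrnas, samples = list(sponges), list(mrnas), list(samples)
    x = m.to_log2().values
    missing = [f for f in (*sponges, *mrnas) if f not in x.index]
    if missing:
        raise UserError(f"features not in matrix: {missing[:5]}")
    n = len(samples)
    if n < 4:
        raise UserError("need at least 4 samples for co-expression")
    a = x.loc[sponges, samples].to_numpy()
    b = x.loc[mrnas, samples].to_numpy()

    def standardize(z):
        mu = z.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan  # constant features never pass thresholds
        return (z - mu) / sd

    r = standardize(a) @ standardize(b).T / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, np.nextafter(0.0, 1.0), p)
    s_idx, m_idx = np.meshgrid(np.arange(len(sponges)), np.arange(len(mrnas)), indexing="ij")
    return pd.DataFrame(
        {
            "sponge": np.asarray(sponges, dtype=object)[s_idx.ravel()],
            "mrna": np.asarray(mrnas, dtype=object)[m_idx.ravel()],
            "pcc": r.ravel(),
            "p_value": p.ravel(),
        }
    )


def build_coexpression_network(
    m: ExpressionMatrix,
    de_sponges,
    de_mrnas,
    samples,
    contrast: str = "",
    r_min: float = 0.2,
    alpha: float = 0.05,
    method: str = "pearson",
    signed: bool = True,
    rna_classes: dict | None = None,
):
    """Retain sponge-mRNA pairs with r > r_min (strict) and P < alpha.

    ``signed=True`` (default) keeps only positively correlated pairs, the
    ceRNA expectation; ``signed=False`` thresholds |r|. ``method`` may be
    ``"spearman"`` to rank-transform the values first.

    Returns (edges, graph): the retained :class:`CoexpressionEdge` list and
    a networkx graph with pcc/p_value/edge_kind attributes.
    """
    de_sponges, de_mrnas = list(de_sponges), list(de_mrnas)
    if not de_sponges or not de_mrnas:
        warnings.warn("empty DE feature list: co-expression network is empty", stacklevel=2)
        return [], nx.Graph()
    if method == "spearman":
        x = m.to_log2()
        ranked = x.values.rank(axis=1)
        m = ExpressionMatrix(ranked, m.sample_groups, scale="log2")
    elif method != "pearson":
        raise UserError(f"unknown correlation method {method!r}")
    table = correlate_pairs(m, de_sponges, de_mrnas, samples)
    keep = (table["pcc"].abs() > r_min) if not signed else (table["pcc"] > r_min)
    keep &= table["p_value"] < alpha
    retained = table[keep.fillna(False)]
    n = len(list(samples))
    edges = [
        CoexpressionEdge(row.sponge, row.mrna, float(row.pcc), float(row.p_value), contrast, n)
        for row in retained.itertuples(index=False)
    ]
    graph = nx.Graph()
    classes = rna_classes or {}
    for e in edges:
        graph.add_node(e.sponge_feature_id, rna_class=classes.get(e.sponge_feature_id, "sponge"))
        graph.add_node(e.mrna_feature_id, rna_class=classes.get(e.mrna_feature_id, "mRNA"))
        graph.add_edge(
            e.sponge_feature_id,
            e.mrna_feature_id,
            pcc=e.pcc,
            p_value=e.p_value,
            edge_kind="coexpression",
        )
    return edges, graph


def edges_to_frame(edges) -> pd.DataFrame:
    """Edge list as a DataFrame (TSV-ready), sorted for determinism."""
    df = pd.DataFrame(
        [
            {
                "sponge_feature_id": e.sponge_feature_id,
                "mrna_feature_id": e.mrna_feature_id,
                "pcc": e.pcc,
                "p_value": e.p_value,
                "contrast": e.contrast,
                "n_samples": e.n_samples,
            }
            for e in edges
        ],
        columns=[
            "sponge_feature_id", "mrna_feature_id", "pcc", "p_value", "contrast", "n_samples",
        ],
    )
    return df.sort_values(["sponge_feature_id", "mrna_feature_id"], ignore_index=True)
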
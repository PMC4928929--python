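"""Single-node centralities and their correlation with evolutionary measures.

Degree centrality is (in + out degree) / (2(n-1)) on the arc
representation, so an undirected edge counts once in each direction.
PageRank runs on the directed weighted graph (damping 0.85, uniform
teleport); betweenness uses directed hop-count shortest paths with the
standard (n-1)(n-2) normalization.

Correlations are reported both per gene and per group (one point per
group at its mean centrality and mean ER/age), mirroring the observation
that grouping genes by function strengthens the centrality-evolution
relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .evo_annotation import EvoAnnotation
from .graph_core import GeneNetwork

__all__ = [
    "CorrelationReport",
    "compute_centralities",
    "correlate",
    "group_centrality_correlation",
]

log = logging.getLogger(__name__)

MEASURES = ("degree_centrality", "pagerank", "betweenness")


@dataclass
class CorrelationReport:
    level: str  # 'gene' or 'group'
    attribute: str
    measure: str
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    degenerate: bool = False


def compute_centralities(
    g: GeneNetwork,
    damping: float = 0.85,
    measures: Sequence[str] = MEASURES,
) -> pd.DataFrame:
    """Per-gene centrality table (rows = genes, sorted; columns = measures)."""
    if g.n == 0:
        raise ValueError("empty network")
    dg = g.to_networkx()
    nodes = g.nodes
    out = pd.DataFrame(index=pd.Index(nodes, name="gene"))
    if "degree_centrality" in measures:
        denom = 2 * (g.n - 1) if g.n > 1 else 1
        out["degree_centrality"] = [
            (dg.in_degree(x) + dg.out_degree(x)) / denom for x in nodes
        ]
    if "pagerank" in measures:
        pr = nx.pagerank(dg, alpha=damping, weight="weight", tol=1e-12, max_iter=500)
        out["pagerank"] = [pr[x] for x in nodes]
    if "betweenness" in measures:
        bt = nx.betweenness_centrality(dg, normalized=True, weight=None)
        out["betweenness"] = [bt[x] for x in nodes]
    return out


def correlate(
    values_x: Mapping[str, float],
    values_y: Mapping[str, float],
    level: str = "gene",
    attribute: str = "",
    measure: str = "",
) -> CorrelationReport:
    """Pearson and Spearman correlation over genes present in both maps."""
    genes = sorted(set(values_x) & set(values_y))
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    x = np.array([values_x[k] for k in genes], dtype=float)
    y = np.array([values_y[k] for k in genes], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("constant input vector; correlation undefined")
        return CorrelationReport(
            level, attribute, measure, len(genes),
            float("nan"), float("nan"), float("nan"), float("nan"),
            degenerate=True,
        )
    pr = stats.pearsonr(x, y)
    sp = stats.spearmanr(x, y)
    return CorrelationReport(
        level=level,
        attribute=attribute,
        measure=measure,
        n=len(genes),
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sp.statistic),
        spearman_p=float(sp.pvalue),
    )


def group_centrality_correlation(
    groups: Mapping[str, Sequence[str]],
    centralities: pd.DataFrame,
    ann: EvoAnnotation,
    measure: str = "pagerank",
    attribute: str = "age",
) -> CorrelationReport:
    """Correlation of per-group mean centrality vs per-group mean ER/age.

    Each named group contributes one point: the mean of ``measure`` and
    the mean of ``attribute`` over its genes having both values.
    """
    if len(groups) < 3:
        raise ValueError(f"need >= 3 groups, got {len(groups)}")
    values = ann.values(attribute)
    cent = centralities[measure]
    mean_c: dict[str, float] = {}
    mean_a: dict[str, float] = {}
    for name, members in groups.items():
        members = [str(x).strip().upper() for x in members]
        usable = [x for x in members if x in cent.index and x in values]
        if not usable:
            raise ValueError(f"group {name!r} has no gene with both values")
        mean_c[name] = float(cent.loc[usable].mean())
        mean_a[name] = float(np.mean([values[x] for x in usable]))
    return correlate(mean_c, mean_a, level="group", attribute=attribute, measure=measure)
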
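"""Global, set, and interset efficiency.

Efficiency measures summarize how quickly information can spread through
a network: the inverse shortest-path distance, averaged over ordered node
pairs, with unreachable pairs contributing zero (so every value lies in
[0, 1] on unweighted networks).

* global efficiency:  E = (1/(n(n-1))) sum_{i != j} 1/d_ij
* set efficiency of M:  E_M = (1/(|M|(|M|-1))) sum_{i,j in M, i != j} 1/d_ij
* interset efficiency from J to I:
    E_IJ = (1/(|I||J| - |I n J|)) sum_{i in I, j in J, i != j} 1/d_ij

where d_ij is the hop-count distance from node j to node i measured on
the **full** network (paths may leave the set).  E_II reduces exactly to
E_I, so the diagonal of an interset-efficiency matrix holds the set
efficiencies.  On directed networks E_IJ is asymmetric.

The cumulative set-efficiency curve ranks genes by ER (coldest first) or
age (oldest first) and traces the SE of the first k genes as the window
grows; shuffled-order controls show what the curve looks like when rank
carries no information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .evo_annotation import EvoAnnotation
from .graph_core import GeneNetwork, shortest_path_distances

__all__ = [
    "EfficiencyResult",
    "SECurve",
    "IEMatrix",
    "global_efficiency",
    "set_efficiency",
    "interset_efficiency",
    "cumulative_se_curve",
    "ie_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class EfficiencyResult:
    """An efficiency value with its pair bookkeeping.

    ``contributing_pairs + unreachable_pairs`` equals the ordered-pair
    denominator of the defining formula.
    """

    value: float
    contributing_pairs: int
    unreachable_pairs: int

    def __float__(self) -> float:
        return self.value


def _inv_distance_block(
    g: GeneNetwork, sources: Sequence[str], targets: Sequence[str]
) -> np.ndarray:
    """Matrix inv_d[j, i] = 1/d(target_i <- source_j); 0 when unreachable
    or on the diagonal (same gene)."""
    oracle = shortest_path_distances(g, sources=list(sources))
    tcol = [oracle._node_idx[t] for t in targets]
    d = oracle.matrix[:, tcol]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # unreachable and d=0 (self) pairs
    return inv


def global_efficiency(g: GeneNetwork) -> EfficiencyResult:
    """Mean inverse distance over all ordered node pairs of the network."""
    n = g.n
    if n < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    nodes = g.nodes
    inv = _inv_distance_block(g, nodes, nodes)
    total_pairs = n * (n - 1)
    contributing = int(np.count_nonzero(inv))
    return EfficiencyResult(
        value=float(inv.sum()) / total_pairs,
        contributing_pairs=contributing,
        unreachable_pairs=total_pairs - contributing,
    )


def set_efficiency(g: GeneNetwork, m) -> EfficiencyResult:
    """Set efficiency of gene set ``m``; distances taken on the full network."""
    members = sorted({str(x).strip().upper() for x in m})
    if len(members) < 2:
        raise ValueError("set efficiency undefined for a singleton or empty set")
    for x in members:
        if x not in g:
            raise KeyError(f"unknown gene {x!r}")
    inv = _inv_distance_block(g, members, members)
    k = len(members)
    total_pairs = k * (k - 1)
    contributing = int(np.count_nonzero(inv))
    return EfficiencyResult(
        value=float(inv.sum()) / total_pairs,
        contributing_pairs=contributing,
        unreachable_pairs=total_pairs - contributing,
    )


def interset_efficiency(g: GeneNetwork, i_set, j_set) -> EfficiencyResult:
    """Interset efficiency from source set J to target set I.

    Sums 1/d(i <- j) over i in I, j in J with i != j; the denominator
    |I||J| - |I n J| corrects for shared genes, so E_II equals E_I.
    """
    targets = sorted({str(x).strip().upper() for x in i_set})
    sources = sorted({str(x).strip().upper() for x in j_set})
    for x in set(targets) | set(sources):
        if x not in g:
            raise KeyError(f"unknown gene {x!r}")
    overlap = len(set(targets) & set(sources))
    denom = len(targets) * len(sources) - overlap
    if denom <= 0:
        raise ValueError("interset efficiency undefined: denominator |I||J|-|InJ| is 0")
    inv = _inv_distance_block(g, sources, targets)
    contributing = int(np.count_nonzero(inv))
    return EfficiencyResult(
        value=float(inv.sum()) / denom,
        contributing_pairs=contributing,
        unreachable_pairs=denom - contributing,
    )


# -- cumulative SE curve -----------------------------------------------


@dataclass
class SECurve:
    """Cumulative set efficiency by attribute rank, with shuffled controls."""

    attribute: str
    ranks: np.ndarray
    se_values: np.ndarray
    control_mean: np.ndarray
    control_sd: np.ndarray
    genes: list[str]  # attribute-ascending order used for the real curve
    control_curves: np.ndarray | None = None  # (n_controls, n_windows)


def _prefix_se(inv: np.ndarray, order: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """SE of the first k genes of ``order`` for each k in ``ranks``.

    Grows the window incrementally, adding only border blocks of the
    inverse-distance matrix.
    """
    out = np.empty(len(ranks))
    total = 0.0
    pos = 0
    current: list[int] = []
    for w, k in enumerate(ranks):
        block = order[pos:k]
        if len(block):
            cur = np.array(current, dtype=np.intp)
            blk = np.asarray(block, dtype=np.intp)
            if cur.size:
                total += inv[np.ix_(blk, cur)].sum() + inv[np.ix_(cur, blk)].sum()
            total += inv[np.ix_(blk, blk)].sum()
            current.extend(block.tolist())
            pos = k
        if k == inv.shape[0]:
            # full window: sum the whole matrix so the value is bitwise
            # identical for every ordering (real curve and all controls)
            out[w] = inv.sum() / (k * (k - 1))
        else:
            out[w] = total / (k * (k - 1))
    return out


def cumulative_se_curve(
    g: GeneNetwork,
    ann: EvoAnnotation,
    attribute: str = "er",
    start: int = 500,
    step: int = 10,
    n_controls: int = 100,
    seed: int = 0,
) -> SECurve:
    """Cumulative SE of the k lowest-ranked genes (coldest/oldest first).

    Windows run k = start, start+step, ... up to all annotated genes (the
    final window is always included, so the last point of every control
    coincides with the real curve).  Controls shuffle the gene order
    ``n_controls`` times on the unchanged network; ties in the real
    ranking are broken by gene symbol.
    """
    values = ann.values(attribute)
    genes = [x for x in g.nodes if x in values]
    n = len(genes)
    if start < 2:
        raise ValueError("start must be >= 2")
    if n < start:
        raise ValueError(f"only {n} annotated genes in network but start={start}")
    order_genes = sorted(genes, key=lambda x: (values[x], x))
    ranks = list(range(start, n + 1, step))
    if ranks[-1] != n:
        ranks.append(n)
    ranks = np.array(ranks, dtype=int)

    inv = _inv_distance_block(g, order_genes, order_genes)
    ident = np.arange(n)
    se = _prefix_se(inv, ident, ranks)

    rng = np.random.default_rng(seed)
    controls = np.empty((n_controls, len(ranks)))
    for c in range(n_controls):
        controls[c] = _prefix_se(inv, rng.permutation(n), ranks)
    return SECurve(
        attribute=attribute,
        ranks=ranks,
        se_values=se,
        control_mean=controls.mean(axis=0),
        control_sd=controls.std(axis=0, ddof=1),
        genes=order_genes,
        control_curves=controls,
    )


# -- interset efficiency matrix ----------------------------------------


@dataclass
class IEMatrix:
    """Interset efficiencies between named groups ordered by mean age.

    ``matrix[i, j]`` is the efficiency from group ``names[j]`` (source,
    column) to group ``names[i]`` (target, row); the diagonal holds each
    group's set efficiency.
    """

    names: list[str]
    mean_ages: np.ndarray
    matrix: np.ndarray


def ie_matrix(
    g: GeneNetwork,
    groups: Mapping[str, Sequence[str]],
    ann: EvoAnnotation,
) -> IEMatrix:
    """Full asymmetric IE matrix over groups sorted oldest (lowest mean age) first."""
    ages = ann.values("age")
    usable: dict[str, list[str]] = {}
    mean_age: dict[str, float] = {}
    for name, members in groups.items():
        mem = sorted({str(x).strip().upper() for x in members} & set(g.nodes))
        aged = [x for x in mem if x in ages]
        if not aged:
            log.warning("group %r has no annotated gene in the network; excluded", name)
            continue
        usable[name] = mem
        mean_age[name] = float(np.mean([ages[x] for x in aged]))
    if len(usable) < 2:
        raise ValueError("need at least 2 usable groups for an IE matrix")
    names = sorted(usable, key=lambda nm: (mean_age[nm], nm))
    k = len(names)
    mat = np.empty((k, k))
    for j, src in enumerate(names):
        for i, tgt in enumerate(names):
            mat[i, j] = interset_efficiency(g, usable[tgt], usable[src]).value
    return IEMatrix(
        names=names,
        mean_ages=np.array([mean_age[nm] for nm in names]),
        matrix=mat,
    )
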
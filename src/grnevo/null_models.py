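"""Randomization null models for edge-level and group-level evolution tests.

Two nulls are implemented:

* **Degree-preserving rewiring** — repeated double-edge swaps that keep
  every node's in- and out-degree exactly.  Swaps are proposed separately
  within the strictly directed arc class and the undirected edge class;
  proposals creating self-loops or duplicate arcs are rejected.  Used to
  ask whether the differences in evolutionary rate (or age) across edges
  are narrower than chance: the width (standard deviation) of the
  edge-difference distribution is compared with the widths from rewired
  replicates via a z-score and an empirical one-tailed p-value with the
  (r+1)/(n+1) estimator.

* **Equal-size random gene sets** — a group's mean ER or age is compared
  with the means of ``n_sets`` random sets of the same size drawn (without
  replacement) from the annotated network genes.  Significance uses a
  normal approximation to the null distribution of set means, which
  permits p-values far below 1/n_sets.  Groups significant at the
  one-tailed ``alpha`` are labeled hot/cold (ER) or young/old (age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit, types
from numba.typed import Dict as NumbaDict
from scipy import stats

from .community import CommunityPartition
from .evo_annotation import EvoAnnotation
from .graph_core import GeneNetwork

__all__ = [
    "EdgeDiffResult",
    "GroupStats",
    "rewire",
    "edge_diff_test",
    "group_mean_test",
    "shuffled_community_control",
]

log = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


# -- numba swap kernels ------------------------------------------------


@njit(cache=False)
def _fill_keys(keys, arr):  # pragma: no cover - trivial numba helper
    for k in arr:
        keys[k] = types.int8(1)


@njit(cache=False)
def _swap_directed(src, dst, keys, n, attempts, seed):
    """Double-edge swaps on strictly directed arcs: (a->b, c->d) -> (a->d, c->b)."""
    np.random.seed(seed)
    n_e = src.shape[0]
    if n_e < 2:
        return
    for _ in range(attempts):
        i = np.random.randint(n_e)
        j = np.random.randint(n_e)
        if i == j:
            continue
        a, b = src[i], dst[i]
        c, d = src[j], dst[j]
        if a == d or c == b:
            continue
        k1 = a * n + d
        k2 = c * n + b
        if k1 in keys or k2 in keys:
            continue
        del keys[a * n + b]
        del keys[c * n + d]
        keys[k1] = types.int8(1)
        keys[k2] = types.int8(1)
        dst[i] = d
        dst[j] = b


@njit(cache=False)
def _swap_undirected(ea, eb, keys, n, attempts, seed):
    """Double-edge swaps on undirected edges, random re-pairing orientation."""
    np.random.seed(seed)
    n_e = ea.shape[0]
    if n_e < 2:
        return
    for _ in range(attempts):
        i = np.random.randint(n_e)
        j = np.random.randint(n_e)
        if i == j:
            continue
        a, b = ea[i], eb[i]
        c, d = ea[j], eb[j]
        if np.random.randint(2) == 0:
            p, q, r, s = a, d, c, b
        else:
            p, q, r, s = a, c, b, d
        if p == q or r == s:
            continue
        if (p == r and q == s) or (p == s and q == r):
            continue
        if p * n + q in keys or q * n + p in keys:
            continue
        if r * n + s in keys or s * n + r in keys:
            continue
        del keys[a * n + b]
        del keys[b * n + a]
        del keys[c * n + d]
        del keys[d * n + c]
        keys[p * n + q] = types.int8(1)
        keys[q * n + p] = types.int8(1)
        keys[r * n + s] = types.int8(1)
        keys[s * n + r] = types.int8(1)
        ea[i], eb[i] = p, q
        ea[j], eb[j] = r, s


class _ArcArrays:
    """Index-array view of a network for fast repeated rewiring."""

    def __init__(self, g: GeneNetwork):
        self.nodes = g.nodes
        self.n = len(self.nodes)
        idx = {x: i for i, x in enumerate(self.nodes)}
        dsrc, ddst, dw = [], [], []
        for u, v, w in g.directed_arcs():
            dsrc.append(idx[u])
            ddst.append(idx[v])
            dw.append(w)
        ua, ub, uw = [], [], []
        for u, v, w in g.undirected_edges():
            ua.append(idx[u])
            ub.append(idx[v])
            uw.append(w)
        self.dir_src = np.array(dsrc, dtype=np.int64)
        self.dir_dst = np.array(ddst, dtype=np.int64)
        self.dir_w = np.array(dw, dtype=np.float64)
        self.und_a = np.array(ua, dtype=np.int64)
        self.und_b = np.array(ub, dtype=np.int64)
        self.und_w = np.array(uw, dtype=np.float64)

    def all_keys(self, a=None, b=None, s=None, t=None) -> np.ndarray:
        a = self.und_a if a is None else a
        b = self.und_b if b is None else b
        s = self.dir_src if s is None else s
        t = self.dir_dst if t is None else t
        n = self.n
        return np.concatenate([s * n + t, a * n + b, b * n + a]).astype(np.int64)

    def rewired(self, n_swaps_dir: int, n_swaps_und: int, seed: int):
        """Return rewired copies (dir_src, dir_dst, und_a, und_b)."""
        s = self.dir_src.copy()
        t = self.dir_dst.copy()
        a = self.und_a.copy()
        b = self.und_b.copy()
        keys = NumbaDict.empty(types.int64, types.int8)
        _fill_keys(keys, self.all_keys())
        rng = np.random.default_rng(seed)
        seed_d = int(rng.integers(_MAX_SEED))
        seed_u = int(rng.integers(_MAX_SEED))
        _swap_directed(s, t, keys, self.n, int(n_swaps_dir), seed_d)
        _swap_undirected(a, b, keys, self.n, int(n_swaps_und), seed_u)
        return s, t, a, b


def rewire(
    g: GeneNetwork,
    n_swaps: int | None = None,
    seed: int = 0,
) -> GeneNetwork:
    """Degree-preserving randomization of ``g`` by double-edge swaps.

    ``n_swaps`` counts swap *attempts* per edge class (rejected proposals
    included); the default is 10x the class size.  In- and out-degrees of
    every node are preserved exactly; weights travel with the arc whose
    source stub they belonged to.
    """
    if n_swaps is not None and n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    arrs = _ArcArrays(g)
    n_dir = len(arrs.dir_src)
    n_und = len(arrs.und_a)
    if n_dir < 2:
        log.warning("fewer than 2 strictly directed arcs; directed class not rewired")
    if n_und < 2:
        log.warning("fewer than 2 undirected edges; undirected class not rewired")
    sw_dir = 10 * n_dir if n_swaps is None else n_swaps
    sw_und = 10 * n_und if n_swaps is None else n_swaps
    s, t, a, b = arrs.rewired(sw_dir, sw_und, seed)
    out = GeneNetwork()
    for gene in arrs.nodes:
        out.add_node(gene)
    nodes = arrs.nodes
    for i in range(n_dir):
        out.add_edge(nodes[s[i]], nodes[t[i]], weight=arrs.dir_w[i], directed=True)
    for i in range(n_und):
        out.add_edge(nodes[a[i]], nodes[b[i]], weight=arrs.und_w[i], directed=False)
    return out


# -- edge-difference assortativity test --------------------------------


@dataclass
class EdgeDiffResult:
    """Edge-difference distribution vs degree-preserving rewired nulls."""

    attribute: str
    diffs: np.ndarray
    width: float
    null_widths: np.ndarray
    z: float
    p_upper: float
    n_edges: int

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.z)


def _arc_index_lists(arrs: _ArcArrays, s, t, a, b):
    """All directed arcs (source, target) implied by the two edge classes."""
    src = np.concatenate([s, a, b])
    dst = np.concatenate([t, b, a])
    return src, dst


def edge_diff_test(
    g: GeneNetwork,
    ann: EvoAnnotation,
    attribute: str = "er",
    n_random: int = 200,
    seed: int = 0,
    n_swaps: int | None = None,
) -> EdgeDiffResult:
    """Width of the edge-wise attribute-difference distribution vs rewired nulls.

    For every arc j->i with both endpoints annotated, the difference
    value(j) - value(i) is recorded; the test statistic is the standard
    deviation ("width") of these differences.  ``n_random`` rewired
    replicates give the null distribution of widths:
    ``z = (width - mean(null)) / sd(null)`` and the one-tailed empirical
    ``p_upper = (r + 1) / (n_random + 1)`` with ``r`` the number of null
    widths at or below the real width.  A strongly negative z means
    connected genes are more similar than degree-matched chance.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    values = ann.values(attribute)
    arrs = _ArcArrays(g)
    vals = np.full(arrs.n, np.nan)
    for i, gene in enumerate(arrs.nodes):
        if gene in values:
            vals[i] = values[gene]

    def widths(src, dst):
        d = vals[src] - vals[dst]
        d = d[np.isfinite(d)]
        return d, float(np.std(d)) if d.size else float("nan")

    src0, dst0 = _arc_index_lists(arrs, arrs.dir_src, arrs.dir_dst, arrs.und_a, arrs.und_b)
    diffs, width = widths(src0, dst0)
    if diffs.size == 0:
        raise ValueError("no arc has both endpoints annotated")

    n_dir = len(arrs.dir_src)
    n_und = len(arrs.und_a)
    sw_dir = 10 * n_dir if n_swaps is None else n_swaps
    sw_und = 10 * n_und if n_swaps is None else n_swaps
    rng = np.random.default_rng(seed)
    null_widths = np.empty(n_random)
    for k in range(n_random):
        rep_seed = int(rng.integers(_MAX_SEED))
        s, t, a, b = arrs.rewired(sw_dir, sw_und, rep_seed)
        src, dst = _arc_index_lists(arrs, s, t, a, b)
        _, null_widths[k] = widths(src, dst)

    null_sd = float(np.std(null_widths, ddof=1)) if n_random > 1 else 0.0
    if np.ptp(null_widths) == 0:  # all replicates identical -> no null variance
        null_sd = 0.0
    if null_sd == 0:
        log.warning("null widths have zero variance; z undefined")
        z = float("nan")
    else:
        z = (width - float(np.mean(null_widths))) / null_sd
    r = int(np.sum(null_widths <= width))
    p_upper = (r + 1) / (n_random + 1)
    return EdgeDiffResult(
        attribute=attribute,
        diffs=diffs,
        width=width,
        null_widths=null_widths,
        z=z,
        p_upper=p_upper,
        n_edges=int(diffs.size),
    )


# -- group mean-shift test ---------------------------------------------


@dataclass
class GroupStats:
    """Mean-shift of a gene group against equal-size random sets."""

    name: str
    size: int
    attribute: str
    group_mean: float
    diff_in_mean: float
    p: float
    label: str
    ks_stat: float
    ks_p: float


_LABELS = {"er": ("hot", "cold"), "age": ("young", "old")}


def group_mean_test(
    g: GeneNetwork,
    ann: EvoAnnotation,
    group,
    attribute: str = "er",
    n_sets: int = 300,
    alpha: float = 1e-3,
    seed: int = 0,
    name: str = "",
) -> GroupStats:
    """Test whether ``group``'s mean ER/age differs from random expectation.

    ``n_sets`` random sets of size ``len(group)`` are drawn without
    replacement from the annotated genes of ``g``.  The one-tailed p-value
    (in the direction of the observed shift) uses a normal approximation
    to the null set-means.  The two-sample KS statistic compares the
    group's value distribution with all annotated values.
    """
    values = ann.values(attribute)
    universe = sorted(x for x in g.nodes if x in values)
    group = sorted({str(x).strip().upper() for x in group})
    missing = [x for x in group if x not in values or x not in g]
    if missing:
        raise ValueError(f"group genes not annotated in network: {missing[:5]}")
    if len(group) < 2:
        raise ValueError("group must contain at least 2 genes")
    if len(group) > len(universe):
        raise ValueError(
            f"group size {len(group)} exceeds annotated universe {len(universe)}"
        )
    # null sets are drawn from the sorted value multiset, so the test
    # depends only on the values and the group size, not on gene labels
    uni_vals = np.sort(np.array([values[x] for x in universe]))
    group_vals = np.array([values[x] for x in group])
    group_mean = float(np.mean(group_vals))

    rng = np.random.default_rng(seed)
    k = len(group)
    set_means = np.empty(n_sets)
    for i in range(n_sets):
        pick = rng.choice(len(universe), size=k, replace=False)
        set_means[i] = uni_vals[pick].mean()

    null_mean = float(np.mean(set_means))
    null_sd = float(np.std(set_means, ddof=1)) if n_sets > 1 else 0.0
    diff = group_mean - null_mean
    if null_sd == 0:
        p = 1.0 if diff == 0 else 0.0
    elif diff > 0:
        p = float(stats.norm.sf(diff / null_sd))
    elif diff < 0:
        p = float(stats.norm.cdf(diff / null_sd))
    else:
        p = 0.5
    hi, lo = _LABELS[attribute]
    if p < alpha and diff > 0:
        label = hi
    elif p < alpha and diff < 0:
        label = lo
    else:
        label = "average"
    ks = stats.ks_2samp(group_vals, uni_vals)
    return GroupStats(
        name=name or f"group[{k}]",
        size=k,
        attribute=attribute,
        group_mean=group_mean,
        diff_in_mean=float(diff),
        p=p,
        label=label,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def shuffled_community_control(
    p: CommunityPartition,
    seed: int = 0,
    g: GeneNetwork | None = None,
) -> CommunityPartition:
    """Shuffle genes across communities, preserving every community's size.

    Modularity of the shuffled partition is recomputed when the network is
    supplied, otherwise reported as NaN.
    """
    from .community import _ordered_communities, directed_modularity

    genes = sorted(p.assignment)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(genes))
    shuffled = [genes[i] for i in perm]
    assignment: dict[str, int] = {}
    pos = 0
    for label, comm in enumerate(p.communities):
        for gene in shuffled[pos : pos + len(comm)]:
            assignment[gene] = label
        pos += len(comm)
    q = directed_modularity(g, assignment) if g is not None else float("nan")
    return CommunityPartition(
        assignment=assignment,
        communities=_ordered_communities(assignment),
        q=q,
    )
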
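"""Synthetic networks with planted evolutionary structure.

The generator emulates the statistical features the analysis relies on,
so every stage of the pipeline can be exercised without external data:

* a stochastic block model whose communities sit on a 1-D core-periphery
  axis: within-community edge probability ``p_in``; between-community
  probability decays geometrically from ``p_out_core`` (core pairs) to
  ``p_out_far`` (peripheral pairs), making core communities denser to all;
* a fraction of edges strictly directed (random orientation), the rest
  undirected, with confidence-score weights;
* per-gene evolutionary rates drawn from community-specific normals
  (cold core, hot periphery) truncated at 0, and integer ages from
  community-specific normals clamped to [0, 12] (old core, young
  periphery);
* annotation sets nested mostly within their home community, with a
  configurable leakage fraction drawn from the rest of the network.

``null_generate`` returns the identical network with ER and age permuted
jointly across genes, destroying every annotation-topology coupling while
preserving the value multisets - the type-I calibration condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .community import CommunityPartition, partition_from_assignment
from .enrichment import CATEGORIES, GeneSetCollection, write_gmt
from .evo_annotation import EvoAnnotation, write_annotation
from .graph_core import GeneNetwork, write_edge_list

__all__ = ["SynthConfig", "generate", "null_generate", "write_bundle"]


@dataclass
class SynthConfig:
    """Generator parameters; defaults give 4 communities of 75 genes on a
    core (cold, old) to periphery (hot, young) axis."""

    community_sizes: tuple[int, ...] = (75, 75, 75, 75)
    p_in: float = 0.15
    p_out_core: float = 0.05
    p_out_far: float = 0.005
    directed_fraction: float = 0.5
    er_centers: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    er_sd: float = 0.5
    age_centers: tuple[float, ...] = (1.0, 4.0, 8.0, 11.0)
    age_sd: float = 1.5
    sets_per_community: int = 3
    set_fraction: float = 0.4
    set_leakage: float = 0.1
    weight_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.community_sizes or sum(self.community_sizes) <= 0:
            raise ValueError("community sizes must sum to a positive count")
        if any(s <= 0 for s in self.community_sizes):
            raise ValueError("community sizes must be positive")
        for p in (self.p_in, self.p_out_core, self.p_out_far, self.directed_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        k = len(self.community_sizes)
        if len(self.er_centers) != k or len(self.age_centers) != k:
            raise ValueError("er_centers and age_centers must match community count")
        if any(c < 0 for c in self.er_centers):
            raise ValueError("er centers must be >= 0")
        if any(not (0 <= c <= 12) for c in self.age_centers):
            raise ValueError("age centers must lie in [0, 12]")
        if not (0.0 <= self.set_leakage < 1.0):
            raise ValueError("set_leakage must be in [0, 1)")

    @property
    def n_genes(self) -> int:
        return int(sum(self.community_sizes))


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _outreach(cfg: SynthConfig, c: int) -> float:
    """Per-community outreach rate, interpolating p_out_core -> p_out_far
    with the community's peripherality c/(K-1) (core=0 ... periphery=K-1)."""
    k = len(cfg.community_sizes)
    if k < 2:
        return cfg.p_out_core
    t = c / (k - 1)
    if cfg.p_out_core <= 0 or cfg.p_out_far <= 0:
        return cfg.p_out_core * (1 - t) + cfg.p_out_far * t
    return float(cfg.p_out_core ** (1 - t) * cfg.p_out_far**t)


def _between_prob(cfg: SynthConfig, a: int, b: int) -> float:
    """Between-community edge probability: geometric mean of the two
    communities' outreach rates, so core communities are denser to all."""
    return float(np.sqrt(_outreach(cfg, a) * _outreach(cfg, b)))


def generate(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[GeneNetwork, EvoAnnotation, CommunityPartition, GeneSetCollection]:
    """Draw one synthetic bundle; fully determined by ``config.seed``
    (or the ``seed`` override)."""
    cfg = config or SynthConfig()
    if seed is not None:
        cfg = SynthConfig(**{**cfg.__dict__, "seed": int(seed)})
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    names = _gene_names(n)
    labels = np.repeat(np.arange(len(cfg.community_sizes)), cfg.community_sizes)

    # edge probabilities per node pair, from the block structure
    k = len(cfg.community_sizes)
    block_p = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            block_p[a, b] = cfg.p_in if a == b else _between_prob(cfg, a, b)
    pair_p = block_p[labels][:, labels]

    g = GeneNetwork()
    for nm in names:
        g.add_node(nm)
    iu, ju = np.triu_indices(n, k=1)
    draw = rng.random(iu.shape[0])
    present = draw < pair_p[iu, ju]
    ei, ej = iu[present], ju[present]
    n_edges = ei.shape[0]
    directed = rng.random(n_edges) < cfg.directed_fraction
    flip = rng.random(n_edges) < 0.5
    wlo, whi = cfg.weight_range
    weights = np.round(rng.uniform(wlo, whi, size=n_edges), 3)
    for e in range(n_edges):
        u, v = (ej[e], ei[e]) if (directed[e] and flip[e]) else (ei[e], ej[e])
        g.add_edge(names[u], names[v], weight=float(weights[e]), directed=bool(directed[e]))

    er_raw = rng.normal(np.asarray(cfg.er_centers)[labels], cfg.er_sd)
    er = np.clip(er_raw, 0.0, None)
    age_raw = rng.normal(np.asarray(cfg.age_centers)[labels], cfg.age_sd)
    age = np.clip(np.rint(age_raw), 0, 12).astype(int)
    ann = EvoAnnotation(
        er={names[i]: float(er[i]) for i in range(n)},
        age={names[i]: int(age[i]) for i in range(n)},
    )

    truth = partition_from_assignment(g, {names[i]: int(labels[i]) for i in range(n)})

    sets: dict[str, frozenset[str]] = {}
    cats: dict[str, str] = {}
    for c in range(k):
        home = [names[i] for i in range(n) if labels[i] == c]
        away = [names[i] for i in range(n) if labels[i] != c]
        size = max(5, int(round(cfg.set_fraction * len(home))))
        n_leak = int(round(cfg.set_leakage * size))
        n_home = min(size - n_leak, len(home))
        for s in range(cfg.sets_per_community):
            members = list(rng.choice(home, size=n_home, replace=False))
            if n_leak and away:
                members += list(rng.choice(away, size=min(n_leak, len(away)), replace=False))
            name = f"SET_C{c}_{s}"
            sets[name] = frozenset(members)
            cats[name] = CATEGORIES[(c * cfg.sets_per_community + s) % len(CATEGORIES)]
    collection = GeneSetCollection(sets=sets, categories=cats)
    return g, ann, truth, collection


def null_generate(
    config: SynthConfig | None = None, seed: int | None = None
) -> tuple[GeneNetwork, EvoAnnotation, CommunityPartition, GeneSetCollection]:
    """Same network as :func:`generate`, with (ER, age) pairs permuted
    uniformly across genes: annotations carry no topological signal."""
    cfg = config or SynthConfig()
    if seed is not None:
        cfg = SynthConfig(**{**cfg.__dict__, "seed": int(seed)})
    g, ann, truth, collection = generate(cfg)
    rng = np.random.default_rng([cfg.seed, 815])  # independent permutation stream
    genes = sorted(ann.genes)
    perm = rng.permutation(len(genes))
    shuffled = [genes[i] for i in perm]
    ann_null = EvoAnnotation(
        er={shuffled[i]: ann.er[genes[i]] for i in range(len(genes))},
        age={shuffled[i]: ann.age[genes[i]] for i in range(len(genes))},
    )
    return g, ann_null, truth, collection


def write_bundle(
    out_dir,
    g: GeneNetwork,
    ann: EvoAnnotation,
    truth: CommunityPartition,
    sets: GeneSetCollection,
    header_comment: str | None = None,
) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats (TSV + GMT)."""
    from .community import write_partition

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": out / "network.tsv",
        "er": out / "gene_er.tsv",
        "age": out / "gene_age.tsv",
        "truth": out / "true_communities.tsv",
        "gmt": out / "gene_sets.gmt",
    }
    write_edge_list(g, paths["edges"], header_comment=header_comment)
    write_annotation(ann, er_path=paths["er"], age_path=paths["age"])
    write_partition(truth, paths["truth"], header_comment=header_comment)
    write_gmt(sets, paths["gmt"])
    return paths
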
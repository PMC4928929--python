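"""Gene-set over-representation in communities.

A transparent stand-in for functional annotation tools: for each
(community, gene set) pair an upper-tail hypergeometric test asks whether
the overlap is larger than expected for a random draw of the community's
size from the universe, and Benjamini-Hochberg correction is applied
within each community's battery of tests.  Gene sets carry a one-letter
category tag: protein type (P), location of final gene product (L),
biological process (B), or cellular component (C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentRow",
    "hypergeom_enrich",
    "enrich_communities",
    "read_gmt",
    "write_gmt",
]

log = logging.getLogger(__name__)

CATEGORIES = ("P", "L", "B", "C")


@dataclass
class GeneSetCollection:
    """Named gene sets with category tags (P/L/B/C)."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(x).strip().upper() for x in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean
        for name in self.categories:
            if self.categories[name] not in CATEGORIES:
                raise ValueError(
                    f"set {name!r}: category must be one of {CATEGORIES}, "
                    f"got {self.categories[name]!r}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(sorted(self.sets))

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


@dataclass
class EnrichmentRow:
    community: int
    set_name: str
    category: str
    overlap: int
    set_size: int
    community_size: int
    p_raw: float
    p_adjusted: float


def hypergeom_enrich(universe, community, annotation) -> float:
    """Upper-tail hypergeometric p: P(overlap >= observed) for a random
    community of the same size drawn from the universe."""
    universe = {str(x).strip().upper() for x in universe}
    if not universe:
        raise ValueError("empty universe")
    community = {str(x).strip().upper() for x in community} & universe
    annotation = {str(x).strip().upper() for x in annotation} & universe
    overlap = len(community & annotation)
    n_universe = len(universe)
    # P(X >= overlap), X ~ Hypergeom(N=universe, K=annotation, n=community)
    return float(stats.hypergeom.sf(overlap - 1, n_universe, len(annotation), len(community)))


def enrich_communities(
    communities: Sequence[Iterable[str]],
    sets: GeneSetCollection,
    universe: Iterable[str],
    threshold: float = 1e-4,
    top_k: int = 3,
) -> list[EnrichmentRow]:
    """Top enriched gene sets per community after per-community BH correction.

    Returns at most ``top_k`` rows per community with BH-adjusted p below
    ``threshold``, ranked by adjusted then raw p (ties by set name).
    """
    universe = {str(x).strip().upper() for x in universe}
    out: list[EnrichmentRow] = []
    set_names = sorted(sets.sets)
    for idx, comm in enumerate(communities):
        comm_set = {str(x).strip().upper() for x in comm} & universe
        if not comm_set:
            continue
        raw = np.array(
            [hypergeom_enrich(universe, comm_set, sets[nm]) for nm in set_names]
        )
        adj = multipletests(raw, method="fdr_bh")[1]
        rows = [
            EnrichmentRow(
                community=idx,
                set_name=nm,
                category=sets.categories.get(nm, ""),
                overlap=len(comm_set & sets[nm]),
                set_size=len(sets[nm]),
                community_size=len(comm_set),
                p_raw=float(raw[k]),
                p_adjusted=float(adj[k]),
            )
            for k, nm in enumerate(set_names)
            if adj[k] < threshold
        ]
        rows.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.set_name))
        out.extend(rows[:top_k])
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read GMT: name <tab> description (category tag) <tab> genes..."""
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need >= 3 fields")
            name, desc = fields[0], fields[1].strip()
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(x for x in fields[2:] if x.strip())
            if desc in CATEGORIES:
                categories[name] = desc
    return GeneSetCollection(sets=sets, categories=categories)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            cat = collection.categories.get(name, "NA")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{cat}\t{genes}\n")
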
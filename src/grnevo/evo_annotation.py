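"""Per-gene evolutionary rates and ages.

The evolutionary rate (ER) of a gene is the mean over alignment columns of
a per-column rate: the number of different amino-acid residues observed in
the column divided by the total evolutionary time span of the phylogeny,
in units of substitutions per amino-acid site per billion years (By).
Low-ER genes are "cold" (conserved), high-ER genes are "hot".

Gene age is a phylostratigraphic index over an ordered series of 13 clades
branching from the human lineage: 0 is the oldest stratum and 12 the
youngest; a gene's age is the index of the earliest clade containing an
ortholog.

Two residue-count conventions are supported: ``distinct`` (the number of
different residues; the default, which gives a fully conserved column a
nonzero rate 1/span) and ``distinct_minus_one`` (the conventional minimum
substitution count, zero for conserved columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "EvoAnnotation",
    "CladeProfile",
    "UninformativeColumnError",
    "column_rate",
    "gene_er",
    "gene_age",
    "load_annotation",
    "load_clade_profile",
    "write_annotation",
    "N_CLADES",
]

log = logging.getLogger(__name__)

N_CLADES = 13
GAP_CHARS = frozenset("-.?*")
AMBIGUOUS_CHARS = frozenset("XBZJ")
CONVENTIONS = ("distinct", "distinct_minus_one")


class UninformativeColumnError(ValueError):
    """Column has fewer than two unambiguous residues; no rate can be assigned."""


@dataclass
class EvoAnnotation:
    """Per-gene evolutionary rate and age tables.

    Genes missing one attribute are retained with the other; lookups on a
    missing attribute return ``None``.
    """

    er: dict[str, float] = field(default_factory=dict)
    age: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, v in self.er.items():
            if v < 0:
                raise ValueError(f"gene {g}: ER must be >= 0, got {v}")
        for g, a in self.age.items():
            if not (0 <= int(a) <= N_CLADES - 1) or int(a) != a:
                raise ValueError(f"gene {g}: age must be an integer in [0, 12], got {a}")
        self.age = {g: int(a) for g, a in self.age.items()}

    @property
    def genes(self) -> set[str]:
        return set(self.er) | set(self.age)

    def values(self, attribute: str) -> dict[str, float]:
        if attribute == "er":
            return dict(self.er)
        if attribute == "age":
            return {g: float(a) for g, a in self.age.items()}
        raise ValueError(f"unknown attribute {attribute!r} (expected 'er' or 'age')")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class CladeProfile:
    """Ortholog presence/absence over ordered clades (index 0 = oldest)."""

    clades: list[str]
    presence: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        k = len(self.clades)
        for g, vec in self.presence.items():
            vec = np.asarray(vec, dtype=bool)
            if vec.shape != (k,):
                raise ValueError(
                    f"gene {g}: presence vector length {vec.shape} != clade count {k}"
                )
            if not vec.any():
                raise ValueError(f"gene {g}: ortholog absent from every clade")
            self.presence[g] = vec


def column_rate(
    column: Iterable[str],
    total_span: float,
    convention: str = "distinct",
) -> float:
    """Rate of one alignment column: distinct residues over the time span.

    ``total_span`` is the total branch length of the phylogeny in billions
    of years.  Gap and ambiguity characters are excluded from the distinct
    count; a column with no usable residue raises
    :class:`UninformativeColumnError`.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if total_span <= 0:
        raise ValueError(f"total_span must be positive, got {total_span}")
    residues = {
        c.upper()
        for c in column
        if c.upper() not in GAP_CHARS and c.upper() not in AMBIGUOUS_CHARS
    }
    if not residues:
        raise UninformativeColumnError("column contains only gaps/ambiguous residues")
    k = len(residues)
    if convention == "distinct_minus_one":
        k -= 1
    return k / total_span


def total_tree_span(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths, in the tree's time units (By here)."""
    span = tree.length()
    if span <= 0:
        raise ValueError("tree has non-positive total branch length")
    return float(span)


def gene_er(
    alignment,
    tree,
    convention: str = "distinct",
    min_residues: int = 2,
) -> float:
    """Mean per-column rate of a gene's protein multiple alignment.

    ``alignment`` is a path to an aligned FASTA file or a Biopython
    alignment; ``tree`` is a path to a Newick file or a dendropy Tree with
    branch lengths in billions of years.  Columns with fewer than
    ``min_residues`` non-gap residues are skipped as uninformative.
    """
    if isinstance(alignment, (str, bytes)) or hasattr(alignment, "__fspath__"):
        alignment = AlignIO.read(str(alignment), "fasta")
    if isinstance(tree, (str, bytes)) or hasattr(tree, "__fspath__"):
        tree = dendropy.Tree.get(path=str(tree), schema="newick")
    span = total_tree_span(tree)

    aln_taxa = {rec.id for rec in alignment}
    tree_taxa = {t.label.replace(" ", "_") for t in tree.taxon_namespace if t.label}
    if tree_taxa and aln_taxa and not (aln_taxa & tree_taxa):
        log.warning(
            "alignment and tree share no taxon labels; time span taken from tree as given"
        )

    ncol = alignment.get_alignment_length()
    rates = []
    for j in range(ncol):
        column = [rec.seq[j] for rec in alignment]
        non_gap = [c for c in column if c.upper() not in GAP_CHARS]
        if len(non_gap) < min_residues:
            continue
        try:
            rates.append(column_rate(column, span, convention))
        except UninformativeColumnError:
            continue
    if not rates:
        raise ValueError("alignment has no informative columns")
    return float(np.mean(rates))


def gene_age(profile: CladeProfile, gene: str) -> int:
    """Smallest clade index (oldest stratum) with a present ortholog."""
    try:
        vec = profile.presence[gene]
    except KeyError:
        raise KeyError(f"gene {gene!r} not in clade profile") from None
    return int(np.flatnonzero(vec)[0])


def _read_two_column(path, value_name: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'gene\\tvalue'")
            gene, val = fields[0], fields[1]
            if lineno == 1:
                try:
                    float(val)
                except ValueError:
                    continue  # header row
            try:
                out[gene.strip().upper()] = float(val)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric {value_name} {val!r}"
                ) from None
    return out


def load_annotation(er_path=None, age_path=None) -> EvoAnnotation:
    """Load ER and/or age tables (two-column TSV: gene, value) and merge them."""
    er = _read_two_column(er_path, "ER") if er_path is not None else {}
    ages_f = _read_two_column(age_path, "age") if age_path is not None else {}
    age = {g: int(round(v)) for g, v in ages_f.items()}
    if not er and er_path is not None:
        log.warning("ER table %s is empty", er_path)
    if not age and age_path is not None:
        log.warning("age table %s is empty", age_path)
    return EvoAnnotation(er=er, age=age)


def write_annotation(ann: EvoAnnotation, er_path=None, age_path=None) -> None:
    if er_path is not None:
        with open(er_path, "w") as fh:
            fh.write("gene\ter\n")
            for g in sorted(ann.er):
                fh.write(f"{g}\t{ann.er[g]:.6g}\n")
    if age_path is not None:
        with open(age_path, "w") as fh:
            fh.write("gene\tage\n")
            for g in sorted(ann.age):
                fh.write(f"{g}\t{ann.age[g]}\n")


def load_clade_profile(path) -> CladeProfile:
    """Read a presence/absence TSV: gene column then one binary column per
    clade, header row naming clades oldest to youngest."""
    df = pd.read_csv(path, sep="\t")
    clades = [str(c) for c in df.columns[1:]]
    presence = {}
    for _, row in df.iterrows():
        gene = str(row.iloc[0]).strip().upper()
        presence[gene] = np.asarray(row.iloc[1:].to_numpy(), dtype=float).astype(bool)
    return CladeProfile(clades=clades, presence=presence)


def ages_from_profile(profile: CladeProfile) -> dict[str, int]:
    """Vectorized :func:`gene_age` over every gene in the profile."""
    return {g: gene_age(profile, g) for g in profile.presence}
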
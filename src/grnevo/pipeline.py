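"""End-to-end orchestration: load inputs, run every stage, write TSV reports.

``run_all`` executes annotate -> communities -> group stats -> enrichment
-> enriched-group stats -> centrality + correlations -> edge-difference
null test -> efficiency suite, and writes:

* ``communities.tsv``      gene -> community assignment (+ modularity Q)
* ``table1_report.tsv``    community/group evolutionary summary, mirroring
  the community-table layout (label, mean shift and p for ER and age, plus
  the top enriched sets per community)
* ``centrality.tsv``       per-gene degree/PageRank/betweenness
* ``table3_report.tsv``    gene- and group-level centrality-evolution
  correlations (Pearson and Spearman)
* ``edge_diff.tsv``        edge-difference widths vs rewired nulls (ER, age)
* ``se_curve_er.tsv``/``se_curve_age.tsv``  cumulative SE curves + controls
* ``ie_matrix.tsv``        interset efficiencies between enriched groups
* ``spy_order.txt``        community/outdegree node ordering

Every output starts with a comment header recording the seed and a hash
of the run configuration, and reruns with the same seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality as centrality_mod
from . import community as community_mod
from . import efficiency as efficiency_mod
from . import enrichment as enrichment_mod
from . import null_models
from .evo_annotation import EvoAnnotation, load_annotation
from .graph_core import GeneNetwork, load_edge_list

__all__ = ["RunConfig", "PipelineError", "run_all", "load_run_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (flat key=value file format)."""

    edges: str = ""
    er: str | None = None
    age: str | None = None
    gmt: str | None = None
    out_dir: str = "grnevo_out"
    seed: int = 0
    n_random: int = 200  # rewired replicates for the edge-difference test
    n_sets: int = 300  # random sets for the group mean test
    n_controls: int = 100  # shuffled controls for the SE curve
    alpha: float = 1e-3  # one-tailed label threshold
    enrich_threshold: float = 1e-4  # BH-adjusted enrichment cutoff
    top_k_communities: int = 10
    top_k_sets: int = 3
    se_start: int | None = None  # None: 500 when feasible, else n//4
    se_step: int = 10
    damping: float = 0.85

    def __post_init__(self) -> None:
        for name in ("n_random", "n_sets", "n_controls", "top_k_communities", "top_k_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # the output location is not part of the analysis
        blob = repr(sorted(d.items())).encode()
        return hashlib.sha1(blob).hexdigest()[:10]


def load_run_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}: line {lineno}: unknown config key {key!r}")
            if val.lower() in {"none", ""}:
                kwargs[key] = None
            elif key in {"seed", "n_random", "n_sets", "n_controls",
                         "top_k_communities", "top_k_sets", "se_start", "se_step"}:
                kwargs[key] = int(val)
            elif key in {"alpha", "enrich_threshold", "damping"}:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
    return RunConfig(**kwargs)


def _header(cfg: RunConfig) -> str:
    return f"# grnevo seed={cfg.seed} config={cfg.config_hash()}\n"


def _write_df(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def _group_row(stats_er, stats_age) -> dict:
    return {
        "er_label": stats_er.label,
        "er_diff_in_mean": stats_er.diff_in_mean,
        "er_p_value": stats_er.p,
        "age_label": stats_age.label,
        "age_diff_in_mean": stats_age.diff_in_mean,
        "age_p_value": stats_age.p,
    }


TABLE1_COLUMNS = [
    "comm_index", "num_genes", "comm_er", "er_diff_in_mean", "er_p_value",
    "comm_age", "age_diff_in_mean", "age_p_value",
    "group_name", "group_type", "group_num_genes", "benjamini",
    "group_er", "group_er_diff_in_mean", "group_er_p_value",
    "group_age", "group_age_diff_in_mean", "group_age_p_value",
]


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns a bundle of results and output paths."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {k: int(rng.integers(2**31 - 1)) for k in
                   ("communities", "group_stats", "edge_diff", "se_curve")}
    results: dict = {"config": cfg, "outputs": {}}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrap

    # -- load ----------------------------------------------------------
    def _load():
        g = load_edge_list(cfg.edges)
        ann = load_annotation(er_path=cfg.er, age_path=cfg.age)
        sets = enrichment_mod.read_gmt(cfg.gmt) if cfg.gmt else None
        return g, ann, sets

    g, ann, sets = _stage("load")(_load)
    results["network"] = g
    results["annotation"] = ann

    # -- communities ---------------------------------------------------
    def _comm():
        p = community_mod.detect_communities(g, seed=stage_seeds["communities"])
        path = out / "communities.tsv"
        community_mod.write_partition(p, path, header_comment=_header(cfg).strip("# \n"))
        with open(out / "spy_order.txt", "w") as fh:
            fh.write(_header(cfg))
            fh.write("\n".join(community_mod.spy_order(g, p)) + "\n")
        return p

    partition = _stage("communities")(_comm)
    results["partition"] = partition
    results["outputs"]["communities"] = out / "communities.tsv"
    top = community_mod.top_communities(partition, cfg.top_k_communities)

    # -- group stats + enrichment --------------------------------------
    def _table1():
        seed_iter = np.random.default_rng(stage_seeds["group_stats"])
        enriched_rows = []
        if sets is not None:
            enriched_rows = enrichment_mod.enrich_communities(
                top, sets, universe=g.nodes,
                threshold=cfg.enrich_threshold, top_k=cfg.top_k_sets,
            )
        rows = []
        comm_stats = []
        for idx, comm in enumerate(top):
            kw = dict(n_sets=cfg.n_sets, alpha=cfg.alpha)
            st_er = null_models.group_mean_test(
                g, ann, comm, "er", seed=int(seed_iter.integers(2**31 - 1)),
                name=f"community_{idx}", **kw)
            st_age = null_models.group_mean_test(
                g, ann, comm, "age", seed=int(seed_iter.integers(2**31 - 1)),
                name=f"community_{idx}", **kw)
            comm_stats.append((st_er, st_age))
            comm_rows = [r for r in enriched_rows if r.community == idx]
            gr = _group_row(st_er, st_age)
            base = {
                "comm_index": idx, "num_genes": len(comm),
                "comm_er": gr["er_label"], "er_diff_in_mean": gr["er_diff_in_mean"],
                "er_p_value": gr["er_p_value"], "comm_age": gr["age_label"],
                "age_diff_in_mean": gr["age_diff_in_mean"],
                "age_p_value": gr["age_p_value"],
            }
            if not comm_rows:
                rows.append({**base, "group_name": "", "group_type": "",
                             "group_num_genes": "", "benjamini": "",
                             "group_er": "", "group_er_diff_in_mean": "",
                             "group_er_p_value": "", "group_age": "",
                             "group_age_diff_in_mean": "", "group_age_p_value": ""})
            for er_row in comm_rows:
                members = sets[er_row.set_name] & set(g.nodes)
                sg_er = null_models.group_mean_test(
                    g, ann, members, "er", seed=int(seed_iter.integers(2**31 - 1)),
                    name=er_row.set_name, **kw)
                sg_age = null_models.group_mean_test(
                    g, ann, members, "age", seed=int(seed_iter.integers(2**31 - 1)),
                    name=er_row.set_name, **kw)
                sgr = _group_row(sg_er, sg_age)
                rows.append({
                    **base,
                    "group_name": er_row.set_name,
                    "group_type": er_row.category,
                    "group_num_genes": er_row.overlap,
                    "benjamini": er_row.p_adjusted,
                    "group_er": sgr["er_label"],
                    "group_er_diff_in_mean": sgr["er_diff_in_mean"],
                    "group_er_p_value": sgr["er_p_value"],
                    "group_age": sgr["age_label"],
                    "group_age_diff_in_mean": sgr["age_diff_in_mean"],
                    "group_age_p_value": sgr["age_p_value"],
                })
        df = pd.DataFrame(rows, columns=TABLE1_COLUMNS)
        _write_df(df, out / "table1_report.tsv", cfg)
        return comm_stats, enriched_rows

    comm_stats, enriched_rows = _stage("group_stats")(_table1)
    results["community_stats"] = comm_stats
    results["enrichment"] = enriched_rows
    results["outputs"]["table1"] = out / "table1_report.tsv"

    # -- centrality + correlations -------------------------------------
    def _centrality():
        ct = centrality_mod.compute_centralities(g, damping=cfg.damping)
        _write_df(ct.reset_index(), out / "centrality.tsv", cfg)
        groups = None
        if sets is not None and enriched_rows:
            names = sorted({r.set_name for r in enriched_rows})
            groups = {nm: sets[nm] for nm in names}
        reports = []
        for attribute in ("er", "age"):
            values = ann.values(attribute)
            for measure in ct.columns:
                reports.append(centrality_mod.correlate(
                    dict(ct[measure]), values,
                    level="gene", attribute=attribute, measure=measure))
            if groups and len(groups) >= 3:
                for measure in ct.columns:
                    reports.append(centrality_mod.group_centrality_correlation(
                        groups, ct, ann, measure=measure, attribute=attribute))
        df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
        _write_df(df, out / "table3_report.tsv", cfg)
        return ct, reports

    ct, correlations = _stage("centrality")(_centrality)
    results["centralities"] = ct
    results["correlations"] = correlations
    results["outputs"]["table3"] = out / "table3_report.tsv"

    # -- edge-difference null test -------------------------------------
    def _edge_diff():
        rows = []
        res = {}
        for attribute in ("er", "age"):
            if not ann.values(attribute):
                continue
            r = null_models.edge_diff_test(
                g, ann, attribute, n_random=cfg.n_random,
                seed=stage_seeds["edge_diff"])
            res[attribute] = r
            rows.append({
                "attribute": attribute, "n_edges": r.n_edges,
                "width": r.width, "null_mean": float(np.mean(r.null_widths)),
                "null_sd": float(np.std(r.null_widths, ddof=1)),
                "z": r.z, "p_upper": r.p_upper, "n_random": cfg.n_random,
            })
        _write_df(pd.DataFrame(rows), out / "edge_diff.tsv", cfg)
        return res

    results["edge_diff"] = _stage("edge_diff")(_edge_diff)
    results["outputs"]["edge_diff"] = out / "edge_diff.tsv"

    # -- efficiency suite ----------------------------------------------
    def _efficiency():
        glob = efficiency_mod.global_efficiency(g)
        curves = {}
        for attribute in ("er", "age"):
            values = ann.values(attribute)
            n_ann = len([x for x in g.nodes if x in values])
            if n_ann < 10:
                continue
            start = cfg.se_start
            if start is None:
                start = 500 if n_ann >= 600 else max(10, n_ann // 4)
            curve = efficiency_mod.cumulative_se_curve(
                g, ann, attribute, start=start, step=cfg.se_step,
                n_controls=cfg.n_controls, seed=stage_seeds["se_curve"])
            curves[attribute] = curve
            df = pd.DataFrame({
                "rank": curve.ranks, "se": curve.se_values,
                "control_mean": curve.control_mean, "control_sd": curve.control_sd,
            })
            _write_df(df, out / f"se_curve_{attribute}.tsv", cfg)
        iem = None
        if sets is not None:
            names = sorted({r.set_name for r in enriched_rows}) if enriched_rows else []
            groups = {nm: sets[nm] for nm in names}
            if len(groups) < 2:
                groups = {nm: sets[nm] for nm in sets.sets}
            if len(groups) >= 2 and ann.age:
                iem = efficiency_mod.ie_matrix(g, groups, ann)
                df = pd.DataFrame(iem.matrix, index=iem.names, columns=iem.names)
                df.index.name = "target_set"
                _write_df(df, out / "ie_matrix.tsv", cfg, index=True)
        return glob, curves, iem

    glob, curves, iem = _stage("efficiency")(_efficiency)
    results["global_efficiency"] = glob
    results["se_curves"] = curves
    results["ie_matrix"] = iem
    results["outputs"]["ie_matrix"] = out / "ie_matrix.tsv"
    log.info("run complete: %d communities, Q=%.4f, E_global=%.4f",
             len(partition), partition.q, glob.value)
    return results
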
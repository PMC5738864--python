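"""End-to-end orchestration: simulate/load -> select -> networks -> hubs.

Every stage writes its artifact to the output directory so stages are
independently inspectable and re-runnable; a JSON run summary records all
parameters, seeds and counts. Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from plastinet import correlation, differential, glasso, network, synthetic
from plastinet.io import (ExpressionMatrix, GeneAnnotation, log2_transform,
                          read_annotation, read_expression, read_groups)

log = logging.getLogger("plastinet")


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run.

    Numeric defaults are the study's published settings: top 500 genes, 10
    null runs, L1 penalty rho = 30 on the intensity-scale covariance, link
    threshold 1e-4, correlation cutoff 0.95.
    """

    # input: either a synthetic spec or paths to expression + group files
    synthetic: synthetic.SyntheticSpec | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    annotation_path: str | None = None
    scale: str = "raw"
    log_transform: bool = False
    # differential selection
    k: int = 500
    n_null_runs: int = 10
    selection_threshold: float | str = "null"  # "null" or an explicit p cutoff
    # glasso network
    rho: float = 30.0
    penalize_diagonal: bool = True
    link_threshold: float = 1e-4
    # pearson network
    correlation_cutoff: float = 0.95
    absolute_r: bool = False
    # bookkeeping
    seed: int = 0
    outdir: str = "plastinet_run"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("rho", "link_threshold", "correlation_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.synthetic is None and self.expression_path is None:
            raise ValueError("need a synthetic spec or an expression path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            spec_kwargs = dict(raw["synthetic"])
            if "hub_degree" in spec_kwargs:
                spec_kwargs["planted_adjacency"] = synthetic.star_adjacency(
                    int(spec_kwargs.pop("hub_degree")))
            raw["synthetic"] = synthetic.SyntheticSpec(**spec_kwargs)
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.synthetic is not None:
            spec = dataclasses.asdict(self.synthetic)
            spec["planted_adjacency"] = np.asarray(
                spec["planted_adjacency"]).tolist()
            out["synthetic"] = spec
        return out


@dataclass
class RunReport:
    summary: dict
    differential: differential.DifferentialTable
    glasso_network: network.GeneNetwork
    pearson_network: network.GeneNetwork
    glasso_filtered: network.GeneNetwork
    pearson_filtered: network.GeneNetwork
    truth: synthetic.SyntheticDataset | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # ---- input ---------------------------------------------------
        stage = "input"
        truth: synthetic.SyntheticDataset | None = None
        if cfg.synthetic is not None:
            truth = synthetic.generate(cfg.synthetic)
            expr = truth.expression
            truth.write(outdir / "expression.tsv", outdir / "truth.json")
        else:
            group_map = read_groups(cfg.groups_path)
            expr = read_expression(cfg.expression_path, group_map, cfg.scale)
        annotation = (read_annotation(cfg.annotation_path)
                      if cfg.annotation_path else GeneAnnotation())
        if cfg.log_transform:
            expr = log2_transform(expr)
        log.info("input: %d genes x %d samples (scale=%s)",
                 expr.n_genes, expr.n_samples, expr.scale)

        # ---- null threshold + differential table ---------------------
        stage = "null_threshold"
        n_naive = len(expr.samples_in("naive"))
        n_plastic = len(expr.samples_in("plastic"))
        record = differential.null_threshold(
            expr.n_genes, n_naive, n_plastic, cfg.n_null_runs, cfg.seed)
        _write_json(outdir / "null_threshold.json", record.to_dict())
        log.info("null threshold over %d runs: %.3g",
                 record.n_runs, record.threshold)

        stage = "differential"
        table = differential.ttest_per_gene(expr)
        table.write(outdir / "differential.tsv")
        threshold = (record.threshold
                     if cfg.selection_threshold == "null"
                     else float(cfg.selection_threshold))
        selected = differential.select_top(table, min(cfg.k, expr.n_genes),
                                           threshold)
        (outdir / "selected_genes.txt").write_text(
            "\n".join(selected) + ("\n" if selected else ""))
        log.info("selected %d genes at p < %.3g", len(selected), threshold)

        # ---- networks ------------------------------------------------
        stage = "glasso"
        if len(selected) >= 2:
            cov = glasso.sample_covariance(expr, selected)
            est = glasso.glasso_fit(cov, cfg.rho,
                                    penalize_diagonal=cfg.penalize_diagonal)
            gnet = glasso.extract_edges(est, cfg.link_threshold, annotation)
        else:
            gnet = network.network_from_edges([], "glasso",
                                              provenance={"rho": cfg.rho})
        network.export_network(gnet, outdir / "glasso_edges.tsv")

        stage = "pearson"
        if len(selected) >= 2 and expr.n_samples >= 3:
            rmat = correlation.pearson_matrix(expr, selected)
            pnet = correlation.correlation_edges(
                rmat, cfg.correlation_cutoff, annotation,
                absolute=cfg.absolute_r)
        else:
            pnet = network.network_from_edges(
                [], "pearson", provenance={"cutoff": cfg.correlation_cutoff})
        network.export_network(pnet, outdir / "pearson_edges.tsv")
        log.info("glasso: %d genes / %d links; pearson: %d genes / %d links",
                 gnet.n_nodes, gnet.n_edges, pnet.n_nodes, pnet.n_edges)

        # ---- filter, intersect, hubs --------------------------------
        stage = "filter"
        gfilt = network.richness_filter(gnet)
        pfilt = network.richness_filter(pnet)
        network.export_network(gfilt, outdir / "glasso_filtered.tsv")
        network.export_network(gfilt, outdir / "glasso_filtered.graphml",
                               fmt="graphml")
        network.export_network(pfilt, outdir / "pearson_filtered.tsv")
        network.export_network(pfilt, outdir / "pearson_filtered.graphml",
                               fmt="graphml")

        stage = "compare"
        common = sorted(network.intersect_nodes(gfilt, pfilt))
        _write_json(outdir / "intersection.json", common)
        ghubs = network.hub_report(gfilt)
        phubs = network.hub_report(pfilt)
        _write_json(outdir / "hub_glasso.json", ghubs)
        _write_json(outdir / "hub_pearson.json", phubs)

        stage = "summary"
        # outdir is location metadata, not an analysis parameter; leaving it
        # out keeps summaries byte-identical across output locations
        cfg_dict = {k: v for k, v in cfg.to_dict().items() if k != "outdir"}
        summary = {
            "config": cfg_dict,
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_naive": n_naive,
            "n_plastic": n_plastic,
            "scale": expr.scale,
            "null_threshold": record.to_dict(),
            "selection_threshold": threshold,
            "n_selected": len(selected),
            "glasso": {"n_nodes": gnet.n_nodes, "n_edges": gnet.n_edges,
                       "filtered_nodes": gfilt.n_nodes,
                       "filtered_edges": gfilt.n_edges},
            "pearson": {"n_nodes": pnet.n_nodes, "n_edges": pnet.n_edges,
                        "filtered_nodes": pfilt.n_nodes,
                        "filtered_edges": pfilt.n_edges},
            "intersection": common,
            "hub": ghubs[0]["probe_id"] if ghubs else None,
            "hub_pearson": phubs[0]["probe_id"] if phubs else None,
        }
        if truth is not None:
            summary["truth_hub"] = truth.hub_id
        _write_json(outdir / "summary.json", summary)
        log.info("hub (glasso, filtered): %s", summary["hub"])
        return RunReport(summary, table, gnet, pnet, gfilt, pfilt, truth)
    except StageError:
        raise
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise StageError(stage, exc) from exc
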
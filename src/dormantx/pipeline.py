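"""End-to-end orchestration: partition → quantify → filter → annotate →
select → cluster, with stage bookkeeping and a machine-readable summary.

All randomness flows from a single master seed, split deterministically per
stage, so a run is reproduced byte-for-byte by its config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, CountSimConfig, FilterConfig
from .discriminative import select_discriminative_features
from .experiment import CountExperiment
from .filters import (consensus_de, expression_filter, persistent_genes,
                      write_filter_outputs)
from .fixtures import fixture_path
from .gene_sets import (GeneSetCollection, UNANNOTATED, annotate_genes,
                        read_gmt, signature_summary, write_gmt)
from .cluster import cluster_matrix
from .partition import (partition_reads, read_alignment_sam,
                        read_alignment_tsv)
from .quantify import (aggregate_counts, model_fold_changes, normalize_counts,
                       size_factors, tpm_matrix)
from .simulate import GroundTruth, simulate_counts

logger = logging.getLogger(__name__)

STAGE_NAMES = ("partition", "quantify", "filter", "gene_sets",
               "discriminative", "clustering")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    counts_path: Optional[Path] = None
    lengths_path: Optional[Path] = None
    alignment_manifest: Optional[Path] = None
    immune_gmt: Optional[Path] = None
    proliferation_gmt: Optional[Path] = None
    androgen_gmt: Optional[Path] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    sim_config: Optional[CountSimConfig] = None
    partition_mode: str = "strict"
    partition_margin: float = 0.0
    fc_pseudocount: float = 1.0
    top_k: int = 54
    n_trees: int = 1000
    master_seed: int = 0
    outdir: Path = Path("dormantx_out")

    def __post_init__(self) -> None:
        provided = [p is not None
                    for p in (self.counts_path, self.alignment_manifest)]
        if sum(provided) != 1 and self.sim_config is None:
            raise ConfigurationError(
                "exactly one of counts_path or alignment_manifest must be "
                "provided (or a sim_config for synthetic runs)")
        self.outdir = Path(self.outdir)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child of the master seed (< 2^31)."""
        idx = STAGE_NAMES.index(stage)
        child = np.random.SeedSequence(self.master_seed).spawn(
            len(STAGE_NAMES))[idx]
        return int(child.generate_state(1)[0] % (2 ** 31))


def _load_manifest_experiment(config: RunConfig) -> tuple[CountExperiment, dict]:
    """Alignment-input path: partition each sample's reads, then count."""
    manifest = pd.read_csv(config.alignment_manifest, sep="\t")
    required = {"sample", "model_id", "stage", "path", "format"}
    if not required.issubset(manifest.columns):
        raise PipelineError("partition",
                            f"manifest needs columns {sorted(required)}")
    base = Path(config.alignment_manifest).parent
    per_sample_counts: dict[str, pd.Series] = {}
    reports = {}
    for _, row in manifest.iterrows():
        path = base / row["path"]
        if row["format"] == "sam":
            records = read_alignment_sam(path)
        elif row["format"] == "tsv":
            records = read_alignment_tsv(path)
        else:
            raise PipelineError(
                "partition", f"unknown alignment format {row['format']!r} "
                f"for sample {row['sample']!r}")
        retained, report = partition_reads(records,
                                           mode=config.partition_mode,
                                           margin=config.partition_margin)
        reports[row["sample"]] = report.__dict__
        per_sample_counts[row["sample"]] = aggregate_counts(retained)
    genes = sorted(set().union(*(set(c.index)
                                 for c in per_sample_counts.values())))
    counts = pd.DataFrame(
        {s: c.reindex(genes).fillna(0).astype(np.int64)
         for s, c in per_sample_counts.items()},
        index=pd.Index(genes, name="gene"))
    meta = manifest.set_index("sample")[["model_id", "stage"]]
    if config.lengths_path is not None:
        lens = pd.read_csv(config.lengths_path, sep="\t", index_col=0)
        eff = lens.iloc[:, 0].astype(float).reindex(genes)
    else:
        eff = pd.Series(1000.0, index=counts.index)
    experiment = CountExperiment(counts=counts, sample_meta=meta,
                                 eff_length=eff)
    return experiment, reports


def run_pipeline(config: RunConfig,
                 ground_truth: GroundTruth | None = None) -> dict:
    """Execute every stage and write the result bundle to ``config.outdir``.

    Returns the summary dict (also written as ``summary.json``). When a
    simulator ground truth is supplied, the summary gains a recovery block
    comparing planted and recovered DE calls.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"master_seed": config.master_seed,
                     "filter_config": config.filter_config.to_dict(),
                     "stages": {}}
    t0 = time.time()

    # -- input / partition ----------------------------------------------------
    if config.sim_config is not None:
        experiment, truth = simulate_counts(config.sim_config,
                                            config.filter_config)
        ground_truth = ground_truth or truth
        experiment.to_tsv(out / "counts.tsv", out / "eff_lengths.tsv")
        truth.to_tsv(out / "ground_truth.tsv")
        summary["stages"]["partition"] = "skipped (simulated counts input)"
    elif config.alignment_manifest is not None:
        experiment, reports = _load_manifest_experiment(config)
        summary["stages"]["partition"] = reports
        experiment.to_tsv(out / "counts.tsv", out / "eff_lengths.tsv")
    else:
        experiment = CountExperiment.from_tsv(config.counts_path,
                                              config.lengths_path)
        summary["stages"]["partition"] = "skipped (counts input)"
    logger.info("input: %d genes x %d samples", *experiment.counts.shape)

    # -- quantify -------------------------------------------------------------
    try:
        tpm_table = tpm_matrix(experiment)
        factors = size_factors(experiment.counts)
        normalized = normalize_counts(experiment.counts, factors)
        fc_table = model_fold_changes(experiment,
                                      pseudocount=config.fc_pseudocount,
                                      normalized=normalized)
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc
    tpm_table.to_csv(out / "tpm.tsv", sep="\t", float_format="%.6g")
    normalized.to_csv(out / "normalized_counts.tsv", sep="\t",
                      float_format="%.6g")
    fc_table.to_tsv(out / "fold_changes.tsv")
    summary["stages"]["quantify"] = {
        "n_genes": int(experiment.counts.shape[0]),
        "n_samples": int(experiment.counts.shape[1]),
        "n_models": experiment.n_models,
        "size_factors": {k: round(float(v), 6) for k, v in factors.items()},
    }

    # -- filters --------------------------------------------------------------
    try:
        expr = expression_filter(experiment, tpm_table, config.filter_config)
        calls = consensus_de(fc_table, config.filter_config,
                             genes=expr.retained)
        persistent = persistent_genes(experiment, config.filter_config,
                                      normalized=normalized)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    persistent_retained = persistent.loc[expr.retained]
    write_filter_outputs(out, expr.retained, calls, fc_table,
                         persistent_retained,
                         experiment, normalized)
    n_up = sum(c.direction == "up" for c in calls)
    n_down = sum(c.direction == "down" for c in calls)
    summary["stages"]["filter"] = {
        "genes_retained": len(expr.retained),
        "de_total": n_up + n_down, "de_up": n_up, "de_down": n_down,
        "persistent": int(persistent_retained.sum()),
    }

    # -- gene sets ------------------------------------------------------------
    immune_path = config.immune_gmt or fixture_path("immune_groups")
    prolif_path = (config.proliferation_gmt
                   or fixture_path("proliferation_set"))
    androgen_path = config.androgen_gmt or fixture_path("androgen_set")
    try:
        collection = GeneSetCollection(sets=read_gmt(immune_path))
        annotation = annotate_genes(expr.retained, collection)
    except Exception as exc:
        raise PipelineError("gene_sets", str(exc)) from exc
    immune_retained = list(annotation.index[annotation != UNANNOTATED])
    annotation.to_csv(out / "immune_annotation.tsv", sep="\t")
    write_gmt(collection.sets, out / "immune_groups_used.gmt")
    signatures = {}
    for name, path in (("proliferation", prolif_path),
                       ("androgen_responsive", androgen_path)):
        members = [g for s in read_gmt(path).values() for g in s]
        present = [g for g in members if g in expr.retained]
        if len(present) < 2:
            signatures[name] = "skipped (fewer than 2 genes retained)"
            continue
        summ = signature_summary(experiment, normalized, present)
        summ["per_sample"].to_csv(out / f"signature_{name}_per_sample.tsv",
                                  sep="\t", float_format="%.6g")
        summ["per_model"].to_csv(out / f"signature_{name}_per_model.tsv",
                                 sep="\t", float_format="%.6g")
        signatures[name] = {
            "n_genes": len(present),
            "median_paired_log2_shift": round(float(
                summ["per_model"]["paired_log2_shift"].median()), 6),
        }
    de_immune = [c for c in calls
                 if c.direction != "none" and c.gene in set(immune_retained)]
    persistent_immune = [g for g in immune_retained
                         if bool(persistent_retained.get(g, False))]
    summary["stages"]["gene_sets"] = {
        "immune_genes_retained": len(immune_retained),
        "immune_de": len(de_immune),
        "immune_de_up": sum(c.direction == "up" for c in de_immune),
        "immune_de_down": sum(c.direction == "down" for c in de_immune),
        "immune_persistent": len(persistent_immune),
        "signatures": signatures,
    }

    # -- discriminative -------------------------------------------------------
    logmat = np.log2(normalized + 1.0)
    rf_seed = config.stage_seed("discriminative")
    if len(immune_retained) >= 2:
        try:
            labels = [experiment.sample_meta.loc[s, "stage"]
                      for s in logmat.columns]
            ranking = select_discriminative_features(
                logmat.loc[immune_retained], labels,
                n_trees=config.n_trees, seed=rf_seed,
                selection_rule="top_k",
                rule_value=min(config.top_k, len(immune_retained)))
        except Exception as exc:
            raise PipelineError("discriminative", str(exc)) from exc
        ranking.to_tsv(out / "feature_ranking.tsv")
        summary["stages"]["discriminative"] = {
            "seed": rf_seed, "n_candidates": len(immune_retained),
            "n_selected": len(ranking.selected),
            "top_gene": ranking.selected[0] if ranking.selected else None,
        }
        selected = ranking.selected
    else:
        summary["stages"]["discriminative"] = "skipped (<2 immune genes)"
        selected = []

    # -- clustering -----------------------------------------------------------
    de_genes = [c.gene for c in calls if c.direction != "none"]
    cluster_summary = {}
    for label, genes in (("de", de_genes), ("discriminative", selected)):
        if len(genes) < 2:
            cluster_summary[label] = "skipped (<2 genes)"
            continue
        try:
            sub = logmat.loc[genes]
            col_dend, col_order = cluster_matrix(sub, axis="columns")
            row_dend, row_order = cluster_matrix(sub, axis="rows")
        except Exception as exc:
            raise PipelineError("clustering", str(exc)) from exc
        col_dend.to_newick(out / f"cluster_{label}_samples.nwk")
        row_dend.to_newick(out / f"cluster_{label}_genes.nwk")
        (out / f"cluster_{label}_sample_order.txt").write_text(
            "\n".join(col_order) + "\n")
        (out / f"cluster_{label}_gene_order.txt").write_text(
            "\n".join(row_order) + "\n")
        cluster_summary[label] = {
            "n_genes": len(genes),
            "sample_order": col_order,
            "stage_separation": _stage_separation(col_dend, experiment),
        }
    summary["stages"]["clustering"] = cluster_summary

    # -- recovery vs ground truth --------------------------------------------
    if ground_truth is not None:
        planted_up = set(ground_truth.genes_with_direction("up"))
        planted_down = set(ground_truth.genes_with_direction("down"))
        called_up = {c.gene for c in calls if c.direction == "up"}
        called_down = {c.gene for c in calls if c.direction == "down"}
        tp = len(called_up & planted_up) + len(called_down & planted_down)
        called = len(called_up) + len(called_down)
        planted = len(planted_up) + len(planted_down)
        summary["recovery"] = {
            "planted_de": planted, "called_de": called,
            "sensitivity": round(tp / planted, 6) if planted else None,
            "false_discovery_proportion":
                round((called - tp) / called, 6) if called else None,
        }

    logger.info("pipeline finished in %.2fs", time.time() - t0)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _stage_separation(col_dend, experiment: CountExperiment) -> bool:
    """True when the top split of the sample dendrogram is active|dormant."""
    n = len(col_dend.leaves)
    children = {n + t: (a, b) for t, (a, b, _h, _s)
                in enumerate(col_dend.merges)}

    def leaves_under(node: int) -> list[str]:
        if node < n:
            return [col_dend.leaves[node]]
        a, b = children[node]
        return leaves_under(a) + leaves_under(b)

    root_a, root_b = children[n + len(col_dend.merges) - 1]
    stages = []
    for side in (root_a, root_b):
        side_stages = {experiment.sample_meta.loc[s, "stage"]
                       for s in leaves_under(side)}
        stages.append(side_stages)
    return (len(stages[0]) == 1 and len(stages[1]) == 1
            and stages[0] != stages[1])
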
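"""The three gene-classification rules at the heart of the analysis.

* **Expression filter** — within each PDX model, a gene counts as expressed
  when TPM >= ``tpm_min`` AND raw count >= ``count_min`` in *either* that
  model's pre-castration or post-castration sample; genes expressed in at
  least ``min_models_expressed`` models are retained.
* **Consensus differential expression** — a retained gene is called up
  (down) in dormancy when its per-model dormant/active fold change is
  >= ``fc_threshold`` (<= 1/``fc_threshold``) in at least ``min_models_de``
  models, all toward the same direction.
* **Dormancy persistence** — a gene is persistent when its mean normalized
  count is >= ``persistence_floor`` in both stages (averaged across models
  by default). All comparisons are inclusive at the threshold.

These are consensus threshold rules, not hypothesis tests; no p-values are
computed here by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ConfigurationError, FilterConfig
from .experiment import CountExperiment, FoldChangeTable
from .quantify import normalize_counts, stage_means

logger = logging.getLogger(__name__)


@dataclass
class DECall:
    gene: str
    direction: str  # up / down / none
    support: int    # models meeting the rule in the called direction


@dataclass
class ExpressionFilterResult:
    retained: list[str]
    expressed: pd.DataFrame  # genes x models boolean


def expression_filter(experiment: CountExperiment,
                      tpm_table: pd.DataFrame,
                      config: FilterConfig) -> ExpressionFilterResult:
    """Apply the per-model either-stage expression rule and retention cut."""
    config.validate_for(experiment.n_models)
    models = experiment.models
    flags = {}
    for model in models:
        per_stage = []
        for stage in ("active", "dormant"):
            col = experiment.sample_of(model, stage)
            per_stage.append((tpm_table[col] >= config.tpm_min)
                             & (experiment.counts[col] >= config.count_min))
        flags[model] = per_stage[0] | per_stage[1]
    expressed = pd.DataFrame(flags, index=experiment.genes)
    retained_mask = expressed.sum(axis=1) >= config.min_models_expressed
    retained = list(experiment.genes[retained_mask])
    return ExpressionFilterResult(retained=retained, expressed=expressed)


def consensus_de(fc_table: FoldChangeTable,
                 config: FilterConfig,
                 genes: list[str] | None = None) -> list[DECall]:
    """Call consensus differential expression from per-model fold changes."""
    fc = fc_table.fc if genes is None else fc_table.fc.loc[genes]
    n_models = fc.shape[1]
    if config.min_models_de > n_models:
        raise ConfigurationError(
            f"min_models_de={config.min_models_de} exceeds the number of "
            f"models ({n_models})")
    up_support = (fc >= config.fc_threshold).sum(axis=1)
    down_support = (fc <= 1.0 / config.fc_threshold).sum(axis=1)
    calls: list[DECall] = []
    for gene in fc.index:
        up_ok = up_support[gene] >= config.min_models_de
        down_ok = down_support[gene] >= config.min_models_de
        if up_ok and down_ok:
            # possible only when min_models_de <= n_models / 2
            logger.warning(
                "gene %s qualifies in both directions (up support %d, down "
                "support %d); called none", gene, up_support[gene],
                down_support[gene])
            calls.append(DECall(gene, "none", 0))
        elif up_ok:
            calls.append(DECall(gene, "up", int(up_support[gene])))
        elif down_ok:
            calls.append(DECall(gene, "down", int(down_support[gene])))
        else:
            calls.append(DECall(gene, "none", 0))
    return calls


def persistent_genes(experiment: CountExperiment,
                     config: FilterConfig,
                     normalized: pd.DataFrame | None = None) -> pd.Series:
    """Flag genes whose stage means stay at or above the persistence floor.

    With ``persistence_scope='across'`` (default) the mean is over models
    per stage; ``'per_model'`` requires the floor in every model's own pair.
    """
    if config.persistence_on_normalized and normalized is None:
        normalized = normalize_counts(experiment.counts)
    values = normalized if config.persistence_on_normalized else None
    means = stage_means(experiment, normalized=values,
                        scope=("across" if config.persistence_scope == "across"
                               else "per_model"))
    if config.persistence_scope == "across":
        flag = ((means["active"] >= config.persistence_floor)
                & (means["dormant"] >= config.persistence_floor))
    else:
        flag = ((means["active"] >= config.persistence_floor).all(axis=1)
                & (means["dormant"] >= config.persistence_floor).all(axis=1))
    flag.name = "persistent"
    return flag


# -- tabular outputs ----------------------------------------------------------

def de_calls_frame(calls: list[DECall],
                   fc_table: FoldChangeTable | None = None) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(c.gene, c.direction, c.support) for c in calls],
        columns=["gene", "direction", "support"]).set_index("gene")
    if fc_table is not None:
        fc = fc_table.fc.loc[frame.index]
        fc.columns = [f"fc_{m}" for m in fc.columns]
        frame = frame.join(fc)
    return frame


def write_filter_outputs(outdir: str | Path,
                         retained: list[str],
                         calls: list[DECall],
                         fc_table: FoldChangeTable,
                         persistent: pd.Series,
                         experiment: CountExperiment,
                         normalized: pd.DataFrame) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(retained, name="gene").to_csv(
        outdir / "retained_genes.tsv", sep="\t", index=False)
    de_calls_frame(calls, fc_table).to_csv(
        outdir / "de_calls.tsv", sep="\t", float_format="%.6g")
    means = stage_means(experiment, normalized=normalized, scope="across")
    pers = pd.DataFrame({"active_mean": means["active"],
                         "dormant_mean": means["dormant"],
                         "persistent": persistent})
    pers.index.name = "gene"
    pers.to_csv(outdir / "persistent_genes.tsv", sep="\t",
                float_format="%.6g")
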
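"""The three gene-classification rules, checked against a brute-force
enumeration written directly from their definitions, plus monotonicity and
planted-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from dormantx.config import ConfigurationError, CountSimConfig, FilterConfig
from dormantx.experiment import FoldChangeTable, make_experiment
from dormantx.filters import (consensus_de, expression_filter,
                              persistent_genes)
from dormantx.quantify import normalize_counts
from dormantx.simulate import simulate_counts


# -- independent brute-force oracle (explicit loops over genes/models) --------

def oracle_retained(tpm, counts, models, cfg):
    retained = []
    for gene in tpm.index:
        n_expressed = 0
        for model in models:
            expressed_here = False
            for stage in ("active", "dormant"):
                s = f"{model}_{stage}"
                if (tpm.loc[gene, s] >= cfg.tpm_min
                        and counts.loc[gene, s] >= cfg.count_min):
                    expressed_here = True
            if expressed_here:
                n_expressed += 1
        if n_expressed >= cfg.min_models_expressed:
            retained.append(gene)
    return retained


def oracle_de(fc, cfg):
    calls = {}
    for gene in fc.index:
        up = sum(1 for m in fc.columns if fc.loc[gene, m] >= cfg.fc_threshold)
        down = sum(1 for m in fc.columns
                   if fc.loc[gene, m] <= 1.0 / cfg.fc_threshold)
        if up >= cfg.min_models_de and down >= cfg.min_models_de:
            calls[gene] = "none"
        elif up >= cfg.min_models_de:
            calls[gene] = "up"
        elif down >= cfg.min_models_de:
            calls[gene] = "down"
        else:
            calls[gene] = "none"
    return calls


def oracle_persistent(normalized, models, cfg):
    flags = {}
    for gene in normalized.index:
        means = {}
        for stage in ("active", "dormant"):
            vals = [normalized.loc[gene, f"{m}_{stage}"] for m in models]
            means[stage] = sum(vals) / len(vals)
        flags[gene] = (means["active"] >= cfg.persistence_floor
                       and means["dormant"] >= cfg.persistence_floor)
    return flags


def random_instance(seed, n_genes=20, n_models=5):
    """Counts/TPM/fc drawn to straddle every threshold."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    models = [f"m{j}" for j in range(n_models)]
    counts = rng.integers(0, 25, size=(n_genes, 2 * n_models))
    exp = make_experiment(counts, genes, models,
                          rng.uniform(300, 5000, size=n_genes))
    tpm = pd.DataFrame(rng.uniform(0.0, 3.0, size=(n_genes, 2 * n_models)),
                       index=exp.genes, columns=exp.counts.columns)
    fc = pd.DataFrame(np.exp2(rng.uniform(-3, 3, size=(n_genes, n_models))),
                      index=exp.genes, columns=models)
    normalized = pd.DataFrame(
        rng.uniform(0, 3000, size=(n_genes, 2 * n_models)),
        index=exp.genes, columns=exp.counts.columns)
    return exp, tpm, fc, normalized, models


@pytest.mark.parametrize("seed", range(25))
def test_rules_match_brute_force_enumeration(seed):
    cfg = FilterConfig()
    exp, tpm, fc, normalized, models = random_instance(seed)
    result = expression_filter(exp, tpm, cfg)
    assert result.retained == oracle_retained(tpm, exp.counts, models, cfg)
    calls = {c.gene: c.direction
             for c in consensus_de(FoldChangeTable(fc=fc), cfg)}
    assert calls == oracle_de(fc, cfg)
    flags = persistent_genes(exp, cfg, normalized=normalized)
    assert flags.to_dict() == oracle_persistent(normalized, models, cfg)


# -- pointwise rule checks ----------------------------------------------------

def _experiment_with(tpm_values, count_values):
    n_models = len(tpm_values)
    exp = make_experiment(np.array([count_values]), ["g"],
                          [f"m{j}" for j in range(n_models // 2)],
                          np.array([1000.0]))
    tpm = pd.DataFrame([tpm_values], index=["g"],
                       columns=exp.counts.columns)
    return exp, tpm


def test_expression_requires_tpm_and_count_jointly():
    # TPM passes everywhere but counts of 8 fail the conjunction
    exp, tpm = _experiment_with([5.0] * 10, [8] * 10)
    result = expression_filter(exp, tpm, FilterConfig())
    assert result.retained == []
    assert not result.expressed.any().any()


def test_expression_either_stage_within_each_model():
    # active stage passes in models 1-3 only -> retained at min 3
    tpm_vals = [1.2, 0.0] * 3 + [0.0, 0.0] * 2
    counts = [15, 0] * 3 + [0, 0] * 2
    exp, tpm = _experiment_with(tpm_vals, counts)
    result = expression_filter(exp, tpm, FilterConfig())
    assert result.retained == ["g"]
    # in exactly 2 of 5 models -> dropped
    tpm_vals = [1.2, 0.0] * 2 + [0.0, 0.0] * 3
    counts = [15, 0] * 2 + [0, 0] * 3
    exp, tpm = _experiment_with(tpm_vals, counts)
    assert expression_filter(exp, tpm, FilterConfig()).retained == []


def test_expression_filter_config_exceeding_models():
    exp, tpm = _experiment_with([1.0] * 6, [10] * 6)
    with pytest.raises(ConfigurationError):
        expression_filter(exp, tpm, FilterConfig(min_models_expressed=4))


def _fc_table(rows):
    fc = pd.DataFrame(rows, columns=[f"m{j}" for j in range(len(rows[0]))])
    fc.index = [f"g{i}" for i in range(len(rows))]
    return FoldChangeTable(fc=fc)


def test_consensus_de_directions_and_support():
    calls = consensus_de(_fc_table([
        [2.1, 2.5, 3.0, 1.2, 0.8],      # up, support 3
        [0.4, 0.45, 0.3, 0.9, 2.2],     # down, support 3
        [2.0, 2.0, 2.0, 2.0, 2.0],      # up in all five (inclusive at 2)
        [1.9, 1.9, 1.9, 1.9, 1.9],      # below threshold -> none
    ]), FilterConfig())
    assert [(c.direction, c.support) for c in calls] == [
        ("up", 3), ("down", 3), ("up", 5), ("none", 0)]


def test_conflicting_directions_called_none_with_warning(caplog):
    table = _fc_table([[4.0, 4.0, 0.25, 0.25]])
    with caplog.at_level("WARNING"):
        calls = consensus_de(table, FilterConfig(min_models_de=2))
    assert calls[0].direction == "none"
    assert "both directions" in caplog.text


def test_persistence_floor_inclusive_and_conjunctive():
    cfg = FilterConfig()
    counts = np.array([
        [2000, 1500] * 5,
        [5000, 900] * 5,
        [1024, 1024] * 5,
    ])
    exp = make_experiment(counts, ["ok", "drops", "edge"],
                          [f"m{j}" for j in range(5)],
                          np.full(3, 1000.0))
    flags = persistent_genes(exp, cfg, normalized=exp.counts.astype(float))
    assert flags.to_dict() == {"ok": True, "drops": False, "edge": True}


def test_persistence_per_model_scope_is_stricter():
    counts = np.array([[2000, 2000, 2000, 2000, 900, 2000]])
    exp = make_experiment(counts, ["g"], ["m1", "m2", "m3"],
                          np.array([1000.0]))
    normalized = exp.counts.astype(float)
    across = persistent_genes(exp, FilterConfig(), normalized=normalized)
    per_model = persistent_genes(
        exp, FilterConfig(persistence_scope="per_model"),
        normalized=normalized)
    assert bool(across["g"]) and not bool(per_model["g"])


# -- monotonicity -------------------------------------------------------------

def test_raising_thresholds_never_adds_calls():
    exp, tpm, fc, normalized, _ = random_instance(99)
    table = FoldChangeTable(fc=fc)
    base = {c.gene for c in consensus_de(table, FilterConfig())
            if c.direction != "none"}
    stricter_fc = {c.gene
                   for c in consensus_de(table, FilterConfig(fc_threshold=3))
                   if c.direction != "none"}
    stricter_support = {
        c.gene for c in consensus_de(table, FilterConfig(min_models_de=4))
        if c.direction != "none"}
    assert stricter_fc <= base and stricter_support <= base
    low = persistent_genes(exp, FilterConfig(), normalized=normalized)
    high = persistent_genes(exp, FilterConfig(persistence_floor=2000),
                            normalized=normalized)
    assert set(high[high].index) <= set(low[low].index)


# -- recovery on planted truth ------------------------------------------------

def _call_directions(experiment, cfg):
    from dormantx.quantify import model_fold_changes
    normalized = normalize_counts(experiment.counts)
    fc = model_fold_changes(experiment, normalized=normalized)
    return {c.gene: c.direction for c in consensus_de(fc, cfg)}


def test_planted_de_recovered_with_high_sensitivity():
    cfg = FilterConfig()
    tp = fp = planted_total = called_total = 0
    for seed in range(8):
        sim = CountSimConfig(n_genes=300, de_fold=4.0, nb_dispersion=0.05,
                             include_signature_genes=False,
                             include_immune_genes=False, seed=seed)
        experiment, truth = simulate_counts(sim, cfg)
        calls = _call_directions(experiment, cfg)
        for gene, direction in calls.items():
            planted = truth.gene_de_direction[gene]
            if planted != "none":
                planted_total += 1
                if direction == planted:
                    tp += 1
            if direction != "none":
                called_total += 1
                if direction != planted:
                    fp += 1
    assert tp / planted_total >= 0.95
    assert fp / called_total <= 0.05


def test_two_of_five_planting_called_none():
    cfg = FilterConfig()
    none_calls = planted = 0
    for seed in range(8):
        sim = CountSimConfig(n_genes=300, de_fold=4.0, nb_dispersion=0.05,
                             n_de_models=2, include_signature_genes=False,
                             include_immune_genes=False, seed=seed)
        experiment, truth = simulate_counts(sim, cfg)
        calls = _call_directions(experiment, cfg)
        for gene, direction in truth.gene_de_direction.items():
            if direction != "none":
                planted += 1
                if calls[gene] == "none":
                    none_calls += 1
    assert none_calls / planted >= 0.9
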
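"""Synthetic data with planted ground truth.

Two generators emulate the study's data, since the original RNA-seq is not
publicly deposited:

* :func:`simulate_reads` draws a dual-species read population — human-unique,
  mouse-unique, dual-mapping ("both") and unmapped reads — as alignment
  summaries against a combined reference, for exercising the species
  partitioner.
* :func:`simulate_counts` draws paired pre/post-castration count matrices
  for five PDX models from a negative-binomial model with shared
  dispersion, planting (i) consensus-DE genes shifted by a known fold in a
  known number of models, (ii) highly abundant persistent genes, and
  (iii) proliferation/androgen signature genes reduced post-castration.

Every planted label is recorded in a :class:`GroundTruth` so recovery can
be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigurationError, CountSimConfig, FilterConfig, ReadSimConfig
from .experiment import CountExperiment, make_experiment
from .fixtures import load_fixture
from .partition import AlignmentSummary, Hit


@dataclass
class GroundTruth:
    """Planted labels: one label per read and per gene for each field."""

    read_species: dict[str, str] = field(default_factory=dict)   # human/mouse/both/none
    read_gene: dict[str, Optional[str]] = field(default_factory=dict)
    gene_de_direction: dict[str, str] = field(default_factory=dict)  # up/down/none
    gene_persistent: dict[str, bool] = field(default_factory=dict)
    gene_signature: dict[str, Optional[str]] = field(default_factory=dict)
    gene_de_models: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def genes_with_direction(self, direction: str) -> list[str]:
        return [g for g, d in self.gene_de_direction.items() if d == direction]

    def gene_table(self) -> pd.DataFrame:
        genes = sorted(self.gene_de_direction)
        frame = pd.DataFrame({
            "de_direction": [self.gene_de_direction[g] for g in genes],
            "persistent": [self.gene_persistent.get(g, False) for g in genes],
            "signature": [self.gene_signature.get(g) or "" for g in genes],
            "de_models": [",".join(self.gene_de_models.get(g, ()))
                          for g in genes],
        }, index=pd.Index(genes, name="gene"))
        return frame

    def to_tsv(self, path: str | Path) -> None:
        self.gene_table().to_csv(path, sep="\t")


# -- read simulation ----------------------------------------------------------

def simulate_reads(config: ReadSimConfig,
                   ) -> tuple[list[AlignmentSummary], GroundTruth]:
    """Draw a labelled dual-species read population.

    Category probabilities: ``unmapped_fraction`` unmapped,
    ``ambiguous_fraction`` dual-mapping, and the remaining mass split
    ``human_fraction`` : ``1 − human_fraction`` between human-unique and
    mouse-unique reads. Human-unique mass is therefore
    ``human_fraction · (1 − ambiguous − unmapped)``.
    """
    rng = np.random.default_rng(config.seed)
    p_un = config.unmapped_fraction
    p_both = config.ambiguous_fraction
    rest = 1.0 - p_un - p_both
    probs = [p_un, p_both, rest * config.human_fraction,
             rest * (1.0 - config.human_fraction)]
    categories = rng.choice(4, size=config.n_reads, p=probs)
    human_genes = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    mouse_genes = [f"mg{i:04d}" for i in range(1, config.n_genes + 1)]

    records: list[AlignmentSummary] = []
    truth = GroundTruth()
    width = len(str(config.n_reads))
    for i, cat in enumerate(categories, start=1):
        rid = f"read{i:0{width}d}"
        rec = AlignmentSummary(rid)
        gene: Optional[str] = None
        if cat == 0:
            species = "none"
        elif cat == 1:
            species = "both"
            hg = human_genes[rng.integers(len(human_genes))]
            mg = mouse_genes[rng.integers(len(mouse_genes))]
            hscore = 60.0
            mscore = float(rng.integers(50, 61))
            rec.hits = [Hit("human", hg, hscore), Hit("mouse", mg, mscore)]
        elif cat == 2:
            species = "human"
            gene = human_genes[rng.integers(len(human_genes))]
            rec.hits = [Hit("human", gene, 60.0)]
            if rng.random() < config.multigene_fraction:
                # read ambiguously hits a second human gene: still
                # HUMAN_ONLY for partitioning, discarded by counting
                others = [g for g in human_genes if g != gene]
                second = others[rng.integers(len(others))]
                rec.hits.append(Hit("human", second, 60.0))
                gene = None
        else:
            species = "mouse"
            mg = mouse_genes[rng.integers(len(mouse_genes))]
            rec.hits = [Hit("mouse", mg, 60.0)]
        truth.read_species[rid] = species
        truth.read_gene[rid] = gene
        records.append(rec)
    return records, truth


def reads_for_counts(counts: pd.Series, seed: int = 0,
                     mouse_reads: int = 0, unmapped_reads: int = 0,
                     read_prefix: str = "r") -> list[AlignmentSummary]:
    """Build human-unique reads realizing an exact per-gene allocation.

    Utility for end-to-end tests of the alignment-input path: partitioning
    then counting these records reproduces ``counts`` exactly, with
    optional mouse/unmapped contaminant reads mixed in.
    """
    rng = np.random.default_rng(seed)
    records: list[AlignmentSummary] = []
    n = 0
    for gene, c in counts.items():
        for _ in range(int(c)):
            n += 1
            records.append(AlignmentSummary(
                f"{read_prefix}{n:07d}", [Hit("human", str(gene), 60.0)]))
    for _ in range(mouse_reads):
        n += 1
        records.append(AlignmentSummary(
            f"{read_prefix}{n:07d}", [Hit("mouse", "mg0001", 60.0)]))
    for _ in range(unmapped_reads):
        n += 1
        records.append(AlignmentSummary(f"{read_prefix}{n:07d}", []))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# -- count simulation ---------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (Poisson limit)."""
    if dispersion <= 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(config: CountSimConfig,
                    filter_config: FilterConfig | None = None,
                    ) -> tuple[CountExperiment, GroundTruth]:
    """Draw a paired active/dormant count experiment with planted truth.

    Gene classes are disjoint: signature genes (named from the packaged
    proliferation/androgen placeholder sets) get a post-castration drop of
    ``signature_reduction_log2``; planted up/down genes get the dormant
    mean multiplied/divided by ``de_fold`` in ``n_de_models`` models;
    persistent genes get both stage means pinned at
    ``persistence_floor × persistent_floor_margin``. Everything else is
    null. Per-gene means are shared across models, so the expected
    dormant/active ratio of a planted gene is exactly ``de_fold``.
    """
    if filter_config is None:
        filter_config = FilterConfig()
    config.validate_against(filter_config)
    rng = np.random.default_rng(config.seed)

    special: list[str] = []
    signature_of: dict[str, str] = {}
    if config.include_signature_genes:
        for set_name, fixture in (("proliferation", "proliferation_set"),
                                  ("androgen_responsive", "androgen_set")):
            for members in load_fixture(fixture).values():
                for g in members:
                    special.append(g)
                    signature_of[g] = set_name
    immune_genes: list[str] = []
    if config.include_immune_genes:
        for members in load_fixture("immune_groups").values():
            immune_genes.extend(g for g in members if g not in signature_of)
        special.extend(immune_genes)
    n_generic = config.n_genes - len(special)
    if n_generic < 0:
        raise ConfigurationError(
            f"n_genes={config.n_genes} is smaller than the "
            f"{len(special)} named signature/immune genes")
    genes = special + [f"g{i:05d}" for i in range(1, n_generic + 1)]

    models = [f"model{i + 1}" for i in range(config.n_models)]
    n_up = int(round(config.frac_de_up * config.n_genes))
    n_down = int(round(config.frac_de_down * config.n_genes))
    n_pers = int(round(config.frac_persistent * config.n_genes))
    eligible = np.array([g for g in genes if g not in signature_of])
    if n_up + n_down + n_pers > len(eligible):
        raise ConfigurationError(
            "not enough non-signature genes to plant the requested DE and "
            "persistent classes")
    picked = rng.choice(eligible, size=n_up + n_down + n_pers, replace=False)
    up_genes = set(picked[:n_up])
    down_genes = set(picked[n_up:n_up + n_down])
    pers_genes = set(picked[n_up + n_down:])

    n_de_models = config.n_de_models or config.n_models
    truth = GroundTruth()
    base_log2 = rng.normal(config.baseline_mean_log2, config.mean_sd_log2,
                           size=len(genes))
    active_mean = np.power(2.0, base_log2)
    dormant_mean = np.tile(active_mean[:, None], (1, config.n_models))
    active_mean = np.tile(active_mean[:, None], (1, config.n_models))

    for idx, gene in enumerate(genes):
        direction = "none"
        de_models: tuple[str, ...] = ()
        if gene in up_genes or gene in down_genes:
            direction = "up" if gene in up_genes else "down"
            chosen = rng.choice(config.n_models, size=n_de_models,
                                replace=False)
            de_models = tuple(models[j] for j in sorted(chosen))
            factor = config.de_fold if direction == "up" else 1.0 / config.de_fold
            for j in sorted(chosen):
                dormant_mean[idx, j] = active_mean[idx, j] * factor
        elif gene in pers_genes:
            pinned = (filter_config.persistence_floor
                      * config.persistent_floor_margin)
            active_mean[idx, :] = pinned
            dormant_mean[idx, :] = pinned
        elif gene in signature_of:
            dormant_mean[idx, :] = (active_mean[idx, :]
                                    / 2.0 ** config.signature_reduction_log2)
            # a signature reduction at or beyond the downstream fold
            # threshold is planted consensus-down by construction
            if 2.0 ** config.signature_reduction_log2 >= \
                    filter_config.fc_threshold:
                direction = "down"
                de_models = tuple(models)
        truth.gene_de_direction[gene] = direction
        truth.gene_de_models[gene] = de_models
        truth.gene_persistent[gene] = gene in pers_genes
        truth.gene_signature[gene] = signature_of.get(gene)

    counts = np.empty((len(genes), 2 * config.n_models), dtype=np.int64)
    for j in range(config.n_models):
        counts[:, 2 * j] = _nb_sample(rng, active_mean[:, j],
                                      config.nb_dispersion)
        counts[:, 2 * j + 1] = _nb_sample(rng, dormant_mean[:, j],
                                          config.nb_dispersion)

    eff_length = np.exp(rng.uniform(math.log(300.0), math.log(10_000.0),
                                    size=len(genes)))
    experiment = make_experiment(counts, genes, models, eff_length)
    return experiment, truth
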
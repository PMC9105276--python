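"""Configuration objects for the dormancy-profiling pipeline.

Every tunable threshold of the analysis lives in one of the dataclasses
below, so a run is fully described by its configs plus a master seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the three gene-classification rules.

    A gene is *expressed* in a model when TPM >= ``tpm_min`` and raw count
    >= ``count_min`` in either stage of that model's pre/post pair; it is
    retained when expressed in at least ``min_models_expressed`` models.
    A retained gene is *differentially expressed* when its dormant/active
    fold change is >= ``fc_threshold`` (or <= 1/``fc_threshold``) in the
    same direction in at least ``min_models_de`` models.  A gene is
    *dormancy-persistent* when its mean normalized count is >=
    ``persistence_floor`` in both stages.
    """

    tpm_min: float = 1.0
    count_min: int = 10
    min_models_expressed: int = 3
    fc_threshold: float = 2.0
    min_models_de: int = 3
    persistence_floor: float = 1024.0
    # "across" averages stage means over models; "per_model" requires the
    # floor in every model's own pair.
    persistence_scope: str = "across"
    # persistence on median-of-ratios normalized counts (default) or raw.
    persistence_on_normalized: bool = True

    def __post_init__(self) -> None:
        for name in ("tpm_min", "count_min", "min_models_expressed",
                     "fc_threshold", "min_models_de", "persistence_floor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.persistence_scope not in ("across", "per_model"):
            raise ConfigurationError(
                "persistence_scope must be 'across' or 'per_model', "
                f"got {self.persistence_scope!r}")

    def validate_for(self, n_models: int) -> None:
        if self.min_models_expressed > n_models:
            raise ConfigurationError(
                f"min_models_expressed={self.min_models_expressed} exceeds "
                f"the number of models ({n_models})")
        if self.min_models_de > n_models:
            raise ConfigurationError(
                f"min_models_de={self.min_models_de} exceeds "
                f"the number of models ({n_models})")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ReadSimConfig:
    """Parameters of the dual-species read simulator.

    The simulated population mirrors a xenograft library aligned to a
    combined human+mouse reference: a fraction of reads is unmapped, a
    fraction aligns to both genomes ("both"), and the remainder is split
    between human-unique and mouse-unique reads by ``human_fraction``.
    """

    n_reads: int = 10_000
    human_fraction: float = 0.7
    ambiguous_fraction: float = 0.05
    unmapped_fraction: float = 0.05
    # fraction of human-unique reads hitting more than one human gene
    # (discarded by gene-level counting, mimicking htseq ambiguity).
    multigene_fraction: float = 0.0
    n_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ConfigurationError("n_reads must be a positive integer")
        for name in ("human_fraction", "ambiguous_fraction",
                     "unmapped_fraction", "multigene_fraction"):
            _check_fraction(name, getattr(self, name))
        if self.ambiguous_fraction + self.unmapped_fraction > 1.0:
            raise ConfigurationError(
                "ambiguous_fraction + unmapped_fraction must not exceed 1 "
                f"(got {self.ambiguous_fraction} + {self.unmapped_fraction})")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be a positive integer")


@dataclass(frozen=True)
class CountSimConfig:
    """Parameters of the paired pre/post-castration count simulator.

    Counts are negative-binomial with a shared dispersion; planted classes
    (up/down consensus-DE genes, persistent genes, signature genes) receive
    stage-specific mean shifts recorded in the accompanying ground truth.
    """

    n_models: int = 5
    n_genes: int = 2000
    nb_dispersion: float = 0.05
    baseline_mean_log2: float = 7.0
    mean_sd_log2: float = 1.5
    frac_de_up: float = 0.02
    frac_de_down: float = 0.04
    de_fold: float = 4.0
    # DE genes are planted in this many of the n_models (None = all).
    n_de_models: Optional[int] = None
    frac_persistent: float = 0.01
    persistent_floor_margin: float = 2.0
    signature_reduction_log2: float = 2.0
    include_signature_genes: bool = True
    include_immune_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1 or self.n_genes < 1:
            raise ConfigurationError("n_models and n_genes must be >= 1")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        for name in ("frac_de_up", "frac_de_down", "frac_persistent"):
            _check_fraction(name, getattr(self, name))
        total = self.frac_de_up + self.frac_de_down + self.frac_persistent
        if total > 1.0:
            raise ConfigurationError(
                "frac_de_up + frac_de_down + frac_persistent must not "
                f"exceed 1 (got {total})")
        if self.de_fold < 1.0:
            raise ConfigurationError("de_fold must be >= 1")
        if self.persistent_floor_margin <= 1.0:
            raise ConfigurationError("persistent_floor_margin must be > 1")
        if self.n_de_models is not None and not (
                1 <= self.n_de_models <= self.n_models):
            raise ConfigurationError(
                f"n_de_models must lie in [1, {self.n_models}]")

    def validate_against(self, filters: FilterConfig) -> None:
        if self.de_fold < filters.fc_threshold:
            raise ConfigurationError(
                f"de_fold={self.de_fold} is below the downstream "
                f"fc_threshold={filters.fc_threshold}")
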
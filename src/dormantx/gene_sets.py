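"""Immune gene-group annotation and signature-level stage comparison.

Gene sets travel in GMT format (tab-separated: set name, description,
member symbols). Annotation is exact symbol match against a curated
collection of immunomodulatory gene groups; signature comparison
summarizes log2(normalized count + 1) distributions per sample and paired
per-model shifts, with an optional signed-rank test across signature genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import CountExperiment


class GeneSetError(ValueError):
    pass


class CurationError(GeneSetError):
    """A gene appears in more than one group of a collection."""


class InsufficientDataError(GeneSetError):
    pass


# -- GMT I/O ------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: member symbols} (descriptions dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{ln}: GMT rows need name, description and at "
                    f"least one member")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise GeneSetError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "dormantx") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# -- collections --------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets plus a per-gene group lookup.

    Construction fails if any symbol belongs to two groups, since the
    immune annotation must be unambiguous.
    """

    sets: dict[str, list[str]]
    group_of: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for name, members in self.sets.items():
            seen: set[str] = set()
            for gene in members:
                if gene in seen:
                    raise CurationError(
                        f"gene {gene} listed twice in group {name!r}")
                seen.add(gene)
                if gene in lookup and lookup[gene] != name:
                    raise CurationError(
                        f"gene {gene} belongs to both {lookup[gene]!r} "
                        f"and {name!r}")
                lookup[gene] = name
        self.group_of = lookup

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        return cls(sets=read_gmt(path))

    @property
    def group_names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        return set(self.group_of)


UNANNOTATED = "unannotated"


def annotate_genes(genes: Iterable[str],
                   collection: GeneSetCollection) -> pd.Series:
    """Label each gene with its immune group, or ``unannotated``."""
    genes = list(genes)
    labels = [collection.group_of.get(g, UNANNOTATED) for g in genes]
    return pd.Series(labels, index=pd.Index(genes, name="gene"),
                     name="group")


# -- signature summaries ------------------------------------------------------

def _signature_matrix(normalized: pd.DataFrame,
                      gene_set: Iterable[str],
                      minimum: int) -> pd.DataFrame:
    members = [g for g in gene_set if g in normalized.index]
    if len(members) < minimum:
        raise (GeneSetError if minimum <= 1 else InsufficientDataError)(
            f"only {len(members)} signature genes present in the matrix "
            f"(need >= {minimum})")
    return np.log2(normalized.loc[members] + 1.0)


def signature_summary(experiment: CountExperiment,
                      normalized: pd.DataFrame,
                      gene_set: Iterable[str]) -> dict[str, pd.DataFrame]:
    """Distribution summary of a signature per sample and per-model shift.

    Returns ``per_sample`` (median and quartiles of log2(norm+1) over
    signature genes) and ``per_model`` (median over signature genes of
    log2 dormant − log2 active; negative = reduced in dormancy).
    """
    logmat = _signature_matrix(normalized, gene_set, minimum=2)
    per_sample = pd.DataFrame({
        "q25": logmat.quantile(0.25),
        "median": logmat.median(),
        "q75": logmat.quantile(0.75),
    })
    per_sample.index.name = "sample"
    diffs = {}
    for model in experiment.models:
        act = experiment.sample_of(model, "active")
        dor = experiment.sample_of(model, "dormant")
        diffs[model] = float((logmat[dor] - logmat[act]).median())
    per_model = pd.DataFrame.from_dict(diffs, orient="index",
                                       columns=["paired_log2_shift"])
    per_model.index.name = "model"
    return {"per_sample": per_sample, "per_model": per_model}


def compare_paired_signature(experiment: CountExperiment,
                             normalized: pd.DataFrame,
                             gene_set: Iterable[str],
                             model: str) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test across signature genes.

    Pairs each signature gene's log2(norm+1) in the model's active vs
    dormant sample. An interpretive add-on: the underlying study design
    has one sample per stage per model, so the test treats genes, not
    biological replicates, as the pairing unit.
    """
    logmat = _signature_matrix(normalized, gene_set, minimum=10)
    act = logmat[experiment.sample_of(model, "active")]
    dor = logmat[experiment.sample_of(model, "dormant")]
    diff = (dor - act).to_numpy()
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)
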
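"""Count-matrix container for paired pre/post-castration xenograft samples.

A :class:`CountExperiment` holds a gene x sample integer count matrix, the
per-sample metadata (PDX model id and stage: ``active`` = pre-castration,
``dormant`` = post-castration) and per-gene effective lengths in
nucleotides. Every model must contribute exactly one sample per stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STAGES = ("active", "dormant")


class ExperimentError(ValueError):
    """Raised when a count experiment violates its pairing invariants."""


def sample_name(model_id: str, stage: str) -> str:
    return f"{model_id}_{stage}"


@dataclass
class CountExperiment:
    counts: pd.DataFrame          # genes x samples, non-negative ints
    sample_meta: pd.DataFrame     # index = sample, columns model_id, stage
    eff_length: pd.Series         # per-gene effective length (nt)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ExperimentError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ExperimentError(f"duplicate gene id {dup!r}")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ExperimentError(f"samples without metadata: {sorted(missing)}")
        bad_stage = set(self.sample_meta["stage"]) - set(STAGES)
        if bad_stage:
            raise ExperimentError(f"unknown stage labels: {sorted(bad_stage)}")
        for model, grp in self.sample_meta.groupby("model_id"):
            stages = sorted(grp["stage"])
            if stages != sorted(STAGES):
                raise ExperimentError(
                    f"model {model!r} must have exactly one active and one "
                    f"dormant sample, found stages {stages}")
        self.eff_length = self.eff_length.reindex(self.counts.index)
        if self.eff_length.isna().any():
            missing_g = self.eff_length.index[self.eff_length.isna()][0]
            raise ExperimentError(f"gene {missing_g!r} lacks an effective length")
        if (self.eff_length <= 0).any():
            raise ExperimentError("effective lengths must be positive")

    # -- convenience accessors ------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def models(self) -> list[str]:
        return sorted(self.sample_meta["model_id"].unique())

    @property
    def n_models(self) -> int:
        return len(self.models)

    def sample_of(self, model_id: str, stage: str) -> str:
        sel = self.sample_meta[(self.sample_meta["model_id"] == model_id)
                               & (self.sample_meta["stage"] == stage)]
        if sel.empty:
            raise ExperimentError(f"model {model_id!r} has no {stage} sample")
        return sel.index[0]

    def stage_columns(self, stage: str) -> list[str]:
        return [self.sample_of(m, stage) for m in self.models]

    # -- I/O ------------------------------------------------------------------

    def to_tsv(self, counts_path: str | Path,
               lengths_path: str | Path | None = None) -> None:
        """Write counts (header ``gene<TAB><model>_<stage>``) and lengths."""
        out = self.counts.copy()
        out.index.name = "gene"
        out.to_csv(counts_path, sep="\t")
        if lengths_path is not None:
            lens = self.eff_length.rename("eff_length").to_frame()
            lens.index.name = "gene"
            lens.to_csv(lengths_path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 lengths_path: str | Path | None = None,
                 default_length: float = 1000.0) -> "CountExperiment":
        """Read a counts TSV whose columns are named ``<model>_<stage>``."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = metadata_from_columns(counts.columns)
        if lengths_path is not None:
            lens = pd.read_csv(lengths_path, sep="\t", index_col=0)
            eff = lens.iloc[:, 0].astype(float)
        else:
            eff = pd.Series(default_length, index=counts.index)
        return cls(counts=counts, sample_meta=meta, eff_length=eff)


def metadata_from_columns(columns: Iterable[str]) -> pd.DataFrame:
    """Parse ``<model>_<stage>`` sample names into a metadata frame."""
    rows = []
    for col in columns:
        model, _, stage = col.rpartition("_")
        if stage not in STAGES or not model:
            raise ExperimentError(
                f"sample name {col!r} does not follow <model>_<stage> with "
                f"stage in {STAGES}")
        rows.append((col, model, stage))
    return pd.DataFrame(rows, columns=["sample", "model_id", "stage"]
                        ).set_index("sample")


def make_experiment(counts: np.ndarray, genes: Sequence[str],
                    models: Sequence[str], eff_length: np.ndarray,
                    stage_order: Sequence[str] = STAGES) -> CountExperiment:
    """Assemble an experiment from an array laid out model-major, stage-minor."""
    cols = [sample_name(m, s) for m in models for s in stage_order]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                         columns=cols)
    meta = metadata_from_columns(cols)
    return CountExperiment(counts=frame, sample_meta=meta,
                           eff_length=pd.Series(eff_length, index=frame.index))


@dataclass
class FoldChangeTable:
    """Per-gene, per-model dormant/active fold changes on normalized counts."""

    fc: pd.DataFrame              # genes x models, strictly positive
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if (self.fc.values <= 0).any():
            raise ExperimentError("fold changes must be strictly positive")
        if self.pseudocount <= 0:
            raise ExperimentError("pseudocount must be positive")

    @property
    def models(self) -> list[str]:
        return list(self.fc.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.fc.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.6g")
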
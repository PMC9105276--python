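"""Gene-level quantification and normalization.

Re-expresses the standard bulk RNA-seq quantification stack as explicit
formulas: unique-gene read counting, transcripts-per-million (TPM) from
counts and effective lengths, median-of-ratios size factors, and per-model
dormant/active fold changes on normalized counts.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .experiment import CountExperiment, ExperimentError, FoldChangeTable
from .partition import AlignmentSummary


class QuantificationError(ValueError):
    pass


def aggregate_counts(reads: Iterable[AlignmentSummary],
                     genes: Sequence[str] | None = None) -> pd.Series:
    """Tally retained reads into per-gene counts.

    A read contributes one count to a gene iff its human hits name exactly
    that single gene; reads hitting more than one human gene are ambiguous
    and discarded, mirroring unique-assignment counting.
    """
    tally: dict[str, int] = {}
    for rec in reads:
        targets = rec.human_genes()
        if len(targets) == 1:
            (gene,) = targets
            tally[gene] = tally.get(gene, 0) + 1
    if genes is None:
        genes = sorted(tally)
    counts = pd.Series([tally.get(g, 0) for g in genes],
                       index=pd.Index(genes, name="gene"), dtype=np.int64)
    return counts


def tpm(counts: pd.Series | np.ndarray,
        eff_length: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Transcripts per million: length-normalized rates scaled to 1e6.

    ``tpm_g = (c_g / L_g) / sum_h (c_h / L_h) * 1e6``. An all-zero count
    vector yields all-zero TPM by convention.
    """
    length = np.asarray(eff_length, dtype=float)
    if (length <= 0).any():
        raise QuantificationError("effective lengths must be positive")
    c = np.asarray(counts, dtype=float)
    if c.shape != length.shape:
        raise QuantificationError("counts and lengths must align")
    rate = c / length
    total = rate.sum()
    values = np.zeros_like(rate) if total == 0 else rate / total * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(values, index=counts.index)
    return values


def tpm_matrix(experiment: CountExperiment) -> pd.DataFrame:
    """Per-sample TPM for every sample of an experiment."""
    return experiment.counts.apply(
        lambda col: tpm(col, experiment.eff_length), axis=0)


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors.

    For genes positive in all samples, ``s_j = median_g c_gj / gmean_g``
    where ``gmean_g`` is the gene's across-sample geometric mean; the
    medians are then rescaled so the factors have geometric mean exactly 1,
    which makes normalization idempotent (re-deriving factors from a
    normalized matrix yields all ones). With ``pseudocount > 0`` every
    count is offset first, a fallback for sparse toy matrices with no
    all-positive gene.
    """
    mat = counts.to_numpy(dtype=float) + pseudocount
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise QuantificationError(
            "no gene has positive counts in every sample; pass a "
            "pseudocount (e.g. 0.5) to enable the offset fallback")
    ref = mat[positive]
    log_gmean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_gmean[:, None]
    log_factors = np.median(ratios, axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     factors: pd.Series | None = None,
                     pseudocount: float = 0.0) -> pd.DataFrame:
    """Divide each sample column by its median-of-ratios size factor."""
    if factors is None:
        factors = size_factors(counts, pseudocount=pseudocount)
    return counts / factors


def model_fold_changes(experiment: CountExperiment,
                       pseudocount: float = 1.0,
                       normalized: pd.DataFrame | None = None,
                       ) -> FoldChangeTable:
    """Per-model dormant/active fold change on normalized counts.

    ``fc_gm = (norm_dormant_gm + pseudocount) / (norm_active_gm +
    pseudocount)``. The pseudocount keeps ratios finite for zero counts and
    makes fc = 1 when both stages are zero.
    """
    if pseudocount <= 0:
        raise QuantificationError("pseudocount must be positive")
    if normalized is None:
        normalized = normalize_counts(experiment.counts)
    fc = {}
    for model in experiment.models:
        try:
            act = experiment.sample_of(model, "active")
            dor = experiment.sample_of(model, "dormant")
        except ExperimentError as exc:
            raise ExperimentError(
                f"model {model!r} lacks a complete active/dormant pair"
            ) from exc
        fc[model] = ((normalized[dor] + pseudocount)
                     / (normalized[act] + pseudocount))
    table = pd.DataFrame(fc, index=experiment.genes)
    return FoldChangeTable(fc=table, pseudocount=pseudocount)


def stage_means(experiment: CountExperiment,
                normalized: pd.DataFrame | None = None,
                scope: str = "across") -> dict[str, pd.DataFrame | pd.Series]:
    """Mean (normalized) counts per stage.

    ``across`` averages over models, giving one mean per stage per gene;
    ``per_model`` returns the per-model stage values unaveraged.
    """
    values = normalized if normalized is not None else experiment.counts
    out: dict[str, pd.DataFrame | pd.Series] = {}
    for stage in ("active", "dormant"):
        cols = experiment.stage_columns(stage)
        sub = values[cols].copy()
        sub.columns = experiment.models
        out[stage] = sub.mean(axis=1) if scope == "across" else sub
    return out
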
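"""Random-forest selection of stage-discriminative immune genes.

A forest is trained on all samples (active vs dormant labels; with five
paired models there are only ten samples, so no held-out split is used)
over log2-normalized expression of the annotated immune genes, and genes
are ranked by feature importance. Impurity (Gini) importance is the
default; permutation importance is available because impurity importance
is biased in the presence of correlated features.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance


class SelectionError(ValueError):
    pass


@dataclass
class FeatureRanking:
    importances: pd.Series      # gene -> importance, sums to 1
    selected: list[str]         # ordered by decreasing importance
    selection_rule: str         # top_k | importance_threshold
    rule_value: float
    seed: int
    n_trees: int

    def to_tsv(self, path: str | Path) -> None:
        frame = self.importances.rename("importance").to_frame()
        frame["selected"] = frame.index.isin(self.selected)
        frame.index.name = "gene"
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} n_trees={self.n_trees} "
                     f"rule={self.selection_rule}:{self.rule_value:g}\n")
            frame.to_csv(fh, sep="\t", float_format="%.6g")


def _rank_genes(importances: pd.Series) -> pd.Series:
    """Sort by decreasing importance, ties broken lexicographically."""
    order = sorted(importances.index, key=lambda g: (-importances[g], g))
    return importances.loc[order]


def select_discriminative_features(
        expression: pd.DataFrame,          # genes x samples, log scale
        labels: Sequence[str],             # per-sample active/dormant
        n_trees: int = 1000,
        seed: int = 0,
        selection_rule: str = "top_k",
        rule_value: float = 54,
        importance: str = "impurity") -> FeatureRanking:
    """Rank genes by forest importance and select per the given rule.

    ``rule_value`` is the k for ``top_k`` (54 is the size of the published
    discriminative set) or the minimum importance for
    ``importance_threshold``.
    """
    labels = list(labels)
    if expression.shape[1] != len(labels):
        raise SelectionError("one label per sample column is required")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise SelectionError(
            f"both classes must be present, got only {classes}")
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise SelectionError(f"need >= 2 samples per class, got {counts}")
    if expression.shape[0] < 2:
        raise SelectionError("need >= 2 features")
    if selection_rule not in ("top_k", "importance_threshold"):
        raise SelectionError(f"unknown selection rule {selection_rule!r}")

    X = expression.to_numpy(dtype=float).T      # samples x genes
    y = np.asarray(labels)
    # max_features=None: with ~10 samples, restricting split candidates
    # makes importances reflect bootstrap luck rather than marginal
    # discriminative power; considering every gene at each split keeps the
    # ranking stable at this sample size.
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    max_depth=None, max_features=None)
    forest.fit(X, y)
    if importance == "impurity":
        raw = forest.feature_importances_
    elif importance == "permutation":
        perm = permutation_importance(forest, X, y, n_repeats=25,
                                      random_state=seed)
        raw = np.clip(perm.importances_mean, 0.0, None)
    else:
        raise SelectionError(f"unknown importance kind {importance!r}")
    total = raw.sum()
    norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    ranked = _rank_genes(pd.Series(norm, index=expression.index))

    if selection_rule == "top_k":
        k = int(rule_value)
        selected = list(ranked.index[:k])
    else:
        selected = list(ranked.index[ranked >= rule_value])
    return FeatureRanking(importances=ranked, selected=selected,
                          selection_rule=selection_rule,
                          rule_value=float(rule_value),
                          seed=seed, n_trees=n_trees)
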
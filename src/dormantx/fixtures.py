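"""Packaged fixtures: printed-table transcriptions and gene-set files.

``table1`` — molecular characteristics of the five PDX models (AR/PSA/SYP
status, TMPRSS2-ERG fusion, PTEN protein and allele status).
``table2`` — the 34 immune-related genes called differentially expressed in
dormancy, with family and direction. The printed symbol ``*CD7*4`` (a
typesetting artifact) is normalized to CD74.
``table3`` — the 24 immune-related genes abundantly expressed in both
stages. ``family`` is the canonical group name; ``family_printed``
preserves the published spelling (e.g. "IL Receptors").
``immune_groups`` — a 20-group immunomodulatory gene curation covering
every family in tables 2–3; configurable, not a published appendix copy.
``proliferation_set`` / ``androgen_set`` — small synthetic placeholder
signatures (the published lists are not public), clearly marked as such.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .gene_sets import GeneSetCollection, read_gmt

_FIXTURE_FILES = {
    "table1": "table1.tsv",
    "table2": "table2.tsv",
    "table3": "table3.tsv",
    "immune_groups": "immune_groups.gmt",
    "proliferation_set": "proliferation_set_synthetic.gmt",
    "androgen_set": "androgen_set_synthetic.gmt",
}


class FixtureError(KeyError):
    pass


def fixture_path(name: str) -> Path:
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; available: "
            f"{sorted(_FIXTURE_FILES)}") from None
    return Path(str(resources.files("dormantx").joinpath("data", fname)))


def load_fixture(name: str):
    """Load a packaged fixture table (DataFrame) or gene-set file (dict)."""
    path = fixture_path(name)
    if path.suffix == ".gmt":
        return read_gmt(path)
    return pd.read_csv(path, sep="\t")


def immune_collection() -> GeneSetCollection:
    """The packaged 20-group immune annotation as a collection."""
    return GeneSetCollection(sets=load_fixture("immune_groups"))


def table2_fold_change_replay(fc_magnitude: float = 4.0,
                              n_models: int = 5) -> pd.DataFrame:
    """Fold-change table consistent with the printed table-2 directions.

    For classification replay: each printed Up gene gets ``fc_magnitude``
    in every model, each Down gene ``1/fc_magnitude``, so running the
    consensus rule over this table must reproduce the printed calls.
    """
    table2 = load_fixture("table2")
    rows = {}
    for _, row in table2.iterrows():
        fc = fc_magnitude if row["direction"] == "Up" else 1.0 / fc_magnitude
        rows[row["gene"]] = [fc] * n_models
    frame = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"model{i + 1}" for i in range(n_models)])
    frame.index.name = "gene"
    return frame
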
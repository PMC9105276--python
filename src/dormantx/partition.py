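"""Species partitioning of reads aligned to a combined human+mouse reference.

Xenograft tissue mixes human tumour cells with mouse stroma, so a library
aligned against a concatenated human+mouse reference contains human-unique,
mouse-unique, dual-mapping and unmapped reads. Downstream expression
estimates for the tumour use the human-unique subset. ``strict`` mode drops
every read carrying any mouse hit; ``score_margin`` mode additionally
rescues dual-mapping reads whose best human alignment score beats the best
mouse score by at least a margin.
"""

from __future__ import annotations

import enum
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

SPECIES = ("human", "mouse")


class PartitionError(ValueError):
    pass


class FormatError(ValueError):
    pass


class ReadClass(enum.Enum):
    HUMAN_ONLY = "human_only"
    MOUSE_ONLY = "mouse_only"
    BOTH = "both"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class Hit:
    species: str
    target_id: str
    score: float


@dataclass
class AlignmentSummary:
    """All reference hits of one read, with species tag and alignment score."""

    read_id: str
    hits: list[Hit] = field(default_factory=list)

    def species_present(self) -> set[str]:
        return {h.species for h in self.hits}

    def best_score(self, species: str) -> float:
        scores = [h.score for h in self.hits if h.species == species]
        return max(scores) if scores else float("-inf")

    def human_genes(self) -> set[str]:
        return {h.target_id for h in self.hits if h.species == "human"}


@dataclass
class PartitionReport:
    n_total: int = 0
    n_human_only: int = 0
    n_mouse_only: int = 0
    n_both: int = 0
    n_unmapped: int = 0
    n_retained: int = 0
    mode: str = "strict"
    margin: float = 0.0

    def check(self) -> None:
        parts = (self.n_human_only + self.n_mouse_only
                 + self.n_both + self.n_unmapped)
        if parts != self.n_total:
            raise PartitionError(
                f"category counts {parts} do not sum to total {self.n_total}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def classify_read(record: AlignmentSummary) -> ReadClass:
    """Assign a read to HUMAN_ONLY / MOUSE_ONLY / BOTH / UNMAPPED."""
    present = record.species_present()
    unknown = present - set(SPECIES)
    if unknown:
        raise FormatError(
            f"read {record.read_id!r} carries unknown species tag(s) "
            f"{sorted(unknown)}")
    if not present:
        return ReadClass.UNMAPPED
    if present == {"human"}:
        return ReadClass.HUMAN_ONLY
    if present == {"mouse"}:
        return ReadClass.MOUSE_ONLY
    return ReadClass.BOTH


def partition_reads(records: Sequence[AlignmentSummary],
                    mode: str = "strict",
                    margin: float = 0.0,
                    ) -> tuple[list[AlignmentSummary], PartitionReport]:
    """Split reads by species and return the retained human subset.

    ``strict`` keeps exactly the HUMAN_ONLY reads. ``score_margin`` also
    rescues BOTH reads whose best human score exceeds the best mouse score
    by at least ``margin``; ties (margin not met) stay BOTH and are dropped.
    """
    if len(records) == 0:
        raise PartitionError("no alignment records provided")
    if mode not in ("strict", "score_margin"):
        raise PartitionError(f"unknown partition mode {mode!r}")
    if margin < 0:
        raise PartitionError("margin must be >= 0")

    report = PartitionReport(mode=mode, margin=margin)
    retained: list[AlignmentSummary] = []
    for i, rec in enumerate(records, start=1):
        cls = classify_read(rec)
        report.n_total += 1
        if cls is ReadClass.HUMAN_ONLY:
            report.n_human_only += 1
            retained.append(rec)
        elif cls is ReadClass.MOUSE_ONLY:
            report.n_mouse_only += 1
        elif cls is ReadClass.UNMAPPED:
            report.n_unmapped += 1
        else:
            report.n_both += 1
            if (mode == "score_margin"
                    and rec.best_score("human") - rec.best_score("mouse")
                    >= margin):
                retained.append(rec)
        if i % 100_000 == 0:
            logger.info("partitioned %d reads", i)
    report.n_retained = len(retained)
    report.check()
    return retained, report


# -- TSV dialect --------------------------------------------------------------
# One row per hit: read_id <TAB> species <TAB> target_id <TAB> score.
# Unmapped reads appear once with empty species/target and score 0.

def write_alignment_tsv(records: Iterable[AlignmentSummary],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\ttarget_id\tscore\n")
        for rec in records:
            if not rec.hits:
                fh.write(f"{rec.read_id}\t\t\t0\n")
            for hit in rec.hits:
                fh.write(f"{rec.read_id}\t{hit.species}\t{hit.target_id}\t"
                         f"{hit.score:g}\n")


def read_alignment_tsv(path: str | Path) -> list[AlignmentSummary]:
    records: dict[str, AlignmentSummary] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["read_id", "species"]:
            raise FormatError(
                f"{path}: expected header starting 'read_id\\tspecies'")
        for ln, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{ln}: expected 4 fields")
            read_id, species, target, score = fields
            rec = records.setdefault(read_id, AlignmentSummary(read_id))
            if species == "":
                continue  # explicit unmapped row
            if species not in SPECIES:
                raise FormatError(
                    f"{path}:{ln}: unknown species {species!r} for read "
                    f"{read_id!r}")
            rec.hits.append(Hit(species, target, float(score)))
    return list(records.values())


# -- SAM ingestion ------------------------------------------------------------

def read_alignment_sam(path: str | Path,
                       human_prefix: str = "GRCh38_",
                       mouse_prefix: str = "GRCm38_",
                       ) -> list[AlignmentSummary]:
    """Load a SAM file aligned to a prefix-tagged combined reference.

    Reference names starting with ``human_prefix``/``mouse_prefix`` map to
    species; the alignment score comes from the AS tag when present, else
    mapping quality. Multiple alignment lines per read (secondary hits)
    accumulate on one record.
    """
    import pysam

    records: dict[str, AlignmentSummary] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            rec = records.setdefault(aln.query_name,
                                     AlignmentSummary(aln.query_name))
            if aln.is_unmapped:
                continue
            ref = aln.reference_name or ""
            if ref.startswith(human_prefix):
                species, target = "human", ref[len(human_prefix):]
            elif ref.startswith(mouse_prefix):
                species, target = "mouse", ref[len(mouse_prefix):]
            else:
                raise FormatError(
                    f"reference {ref!r} matches neither prefix "
                    f"{human_prefix!r} nor {mouse_prefix!r} "
                    f"(read {aln.query_name!r})")
            score = (float(aln.get_tag("AS")) if aln.has_tag("AS")
                     else float(aln.mapping_quality))
            rec.hits.append(Hit(species, target, score))
    return list(records.values())


def write_retained_ids(records: Iterable[AlignmentSummary],
                       path: str | Path | TextIO = sys.stdout) -> None:
    lines = "".join(f"{rec.read_id}\n" for rec in records)
    if hasattr(path, "write"):
        path.write(lines)
    else:
        Path(path).write_text(lines)
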
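"""FASTA I/O, residue validation, and labeled train/test dataset loading.

Sequence curation follows the conventions of the TFPM benchmark datasets:
entries containing ambiguous residues (B, X, Z — and, for feature-space
closure, U, O and ``*``) are rejected in strict mode or stripped in lenient
mode.  Strict mode mirrors how the training data were curated; lenient mode
is meant for prediction-time inputs, where one odd residue should not abort
a proteome-wide screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; names the offending entry."""


class ValidationError(ValueError):
    """Raised in strict mode when a sequence contains a non-canonical residue."""

    def __init__(self, record_id: str, residue: str, position: int):
        self.record_id = record_id
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(
            f"record {record_id!r}: non-canonical residue {residue!r} "
            f"at position {position}"
        )


class DatasetError(ValueError):
    """Raised for inconsistent dataset manifests (e.g. duplicate ids)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus an uppercase amino-acid sequence.

    The id is the FASTA header up to the first whitespace; the full header
    is retained as ``description``.
    """

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())


class Partition(str, Enum):
    train = "train"
    test = "test"


class Task(str, Enum):
    TF_vs_nonTF = "TF_vs_nonTF"
    TFPM_vs_TFPNM = "TFPM_vs_TFPNM"


@dataclass
class LabeledDataset:
    """Ordered protein records with parallel binary labels (1 = positive)."""

    records: list[ProteinRecord]
    labels: np.ndarray
    partition: Partition | None = None
    task: Task | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise DatasetError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((self.labels == 0).sum())

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


def read_fasta(path: str | Path, strict: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Multi-line sequences are concatenated; ids are parsed up to the first
    whitespace.  With ``strict=True`` every record must pass
    :func:`validate_record`; with ``strict=False`` records are returned
    as parsed (uppercased) without residue filtering.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    try:
        for entry in SeqIO.parse(str(path), "fasta"):
            seq = str(entry.seq).strip()
            if not seq:
                raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
            rec = ProteinRecord(id=entry.id, sequence=seq, description=entry.description)
            if strict:
                rec = validate_record(rec, strict=True)
            records.append(rec)
    except ValueError as exc:
        if isinstance(exc, (FastaParseError, ValidationError)):
            raise
        raise FastaParseError(f"{path}: {exc}") from exc
    if not records and path.stat().st_size > 0:
        raise FastaParseError(f"{path}: no FASTA entries found (missing '>' header?)")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA; round-trips byte-identically for canonical input."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(entries)


def validate_record(record: ProteinRecord, strict: bool = True) -> ProteinRecord:
    """Validate a record against the 20-residue canonical alphabet.

    Strict mode rejects any record containing a character outside the
    canonical alphabet (including B, X, Z, U, O, ``*``), reporting the first
    offending character and its 1-based position.  Lenient mode strips
    non-canonical characters and logs a warning.
    """
    seq = record.sequence
    if strict:
        for i, ch in enumerate(seq):
            if ch not in CANONICAL_RESIDUES:
                raise ValidationError(record.id, ch, i + 1)
        return record
    cleaned = "".join(ch for ch in seq if ch in CANONICAL_RESIDUES)
    if cleaned != seq:
        n_removed = len(seq) - len(cleaned)
        logger.warning(
            "record %s: stripped %d non-canonical residue(s)", record.id, n_removed
        )
    if not cleaned:
        logger.warning("record %s: empty after stripping non-canonical residues", record.id)
    return ProteinRecord(id=record.id, sequence=cleaned, description=record.description)


def _load_class_files(paths: Sequence[str | Path], base: Path, strict: bool) -> list[ProteinRecord]:
    records: list[ProteinRecord] = []
    for p in paths:
        p = Path(p)
        if not p.is_absolute():
            p = base / p
        recs = read_fasta(p, strict=strict)
        logger.info("loaded %d records from %s", len(recs), p)
        records.extend(recs)
    return records


def load_dataset(
    manifest: str | Path | dict,
    strict: bool = True,
) -> LabeledDataset:
    """Load a labeled dataset from a manifest.

    The manifest is a YAML file (or an equivalent dict) with keys::

        task: TFPM_vs_TFPNM        # optional
        partition: train           # optional
        positive: [tfpm_train.fasta, ...]
        negative: [tfpnm_train.fasta, ...]

    File paths are resolved relative to the manifest's directory.  Positives
    are labeled 1, negatives 0.  Duplicate ids across classes raise
    :class:`DatasetError`.
    """
    if isinstance(manifest, (str, Path)):
        manifest_path = Path(manifest)
        with open(manifest_path) as fh:
            cfg = yaml.safe_load(fh) or {}
        base = manifest_path.parent
    else:
        cfg = dict(manifest)
        base = Path(cfg.pop("base_dir", "."))

    pos_files = cfg.get("positive", []) or []
    neg_files = cfg.get("negative", []) or []
    pos = _load_class_files(pos_files, base, strict)
    neg = _load_class_files(neg_files, base, strict)

    if not pos and not neg:
        logger.warning("manifest defines no sequence files; returning empty dataset")

    pos_ids = {r.id for r in pos}
    dupes = pos_ids & {r.id for r in neg}
    if dupes:
        raise DatasetError(f"ids present in both classes: {sorted(dupes)[:5]}")

    records = pos + neg
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    partition = Partition(cfg["partition"]) if cfg.get("partition") else None
    task = Task(cfg["task"]) if cfg.get("task") else None
    logger.info("dataset loaded: %d positives, %d negatives", len(pos), len(neg))
    return LabeledDataset(records=records, labels=labels, partition=partition, task=task)
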
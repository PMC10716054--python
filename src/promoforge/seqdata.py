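"""Promoter sequence datasets: ingest, validation, windowing, activity.

The central objects are :class:`PromoterRecord` — one fixed-length DNA
sequence with optional strength/realness labels, an activity measurement
(fluorescence intensity per OD600) and a sigma-class annotation — and
:class:`SequenceDataset`, an ordered, id-unique collection of records.

Sequences are restricted to the strict {A, C, G, T} alphabet at ingest:
the downstream encodings (one-hot, pseudo-dinucleotide composition) are
defined only on the four-letter alphabet, so ambiguity codes are rejected
rather than silently mapped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"

__all__ = [
    "PromoterRecord", "SequenceDataset", "StrengthLabel", "RealnessLabel",
    "SigmaClass", "ActivityCall", "read_fasta", "write_fasta",
    "read_activity_table", "write_activity_table", "window_to_50",
    "sample_windows", "extend_promoter", "normalize_activity", "call_active",
]


class StrengthLabel(str, Enum):
    STRONG = "strong"
    WEAK = "weak"
    UNKNOWN = "unknown"


class RealnessLabel(str, Enum):
    REAL = "real"
    FAKE = "fake"
    UNKNOWN = "unknown"


class SigmaClass(str, Enum):
    SIGMA70 = "sigma70"
    NON_SIGMA70 = "non_sigma70"
    UNKNOWN = "unknown"


class ActivityCall(str, Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


def _validate_sequence(seq: str, ident: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(DNA_ALPHABET)
    if bad:
        raise ValueError(
            f"record {ident!r}: sequence contains non-ACGT characters {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter (or non-promoter) sequence with optional annotations."""

    id: str
    sequence: str
    strength_label: StrengthLabel = StrengthLabel.UNKNOWN
    realness_label: RealnessLabel = RealnessLabel.UNKNOWN
    activity: float | None = None
    sigma_class: SigmaClass = SigmaClass.UNKNOWN
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence, self.id))
        for fname, enum_cls in (("strength_label", StrengthLabel),
                                ("realness_label", RealnessLabel),
                                ("sigma_class", SigmaClass)):
            value = getattr(self, fname)
            if not isinstance(value, enum_cls):
                object.__setattr__(self, fname, enum_cls(str(value).lower()))
        if self.activity is not None:
            act = float(self.activity)
            if not np.isfinite(act) or act < 0:
                raise ValueError(
                    f"record {self.id!r}: activity must be finite and >= 0, got {self.activity}"
                )
            object.__setattr__(self, "activity", act)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDataset:
    """Ordered collection of promoter records with unique ids."""

    records: list[PromoterRecord] = field(default_factory=list)
    fixed_length: int | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate record id {dup!r}")
        if self.fixed_length is not None:
            for r in self.records:
                if len(r) != self.fixed_length:
                    raise ValueError(
                        f"record {r.id!r} has length {len(r)}, expected {self.fixed_length}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PromoterRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PromoterRecord:
        return self.records[i]

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def activities(self) -> np.ndarray:
        vals = [r.activity for r in self.records]
        if any(v is None for v in vals):
            raise ValueError("dataset contains records without activity")
        return np.array(vals, dtype=float)

    def subset(self, indices: Sequence[int]) -> "SequenceDataset":
        return SequenceDataset([self.records[i] for i in indices], self.fixed_length)

    @staticmethod
    def from_records(records: Iterable[PromoterRecord],
                     fixed_length: int | None = None) -> "SequenceDataset":
        recs = list(records)
        if fixed_length is None and recs:
            lengths = {len(r) for r in recs}
            if len(lengths) == 1:
                fixed_length = lengths.pop()
        return SequenceDataset(recs, fixed_length)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceDataset:
    """Read a FASTA file into a dataset; sequences are uppercased and
    validated against the strict ACGT alphabet."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ValueError(f"{path}: not FASTA — line 1 does not start with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(PromoterRecord(id=rec.id, sequence=str(rec.seq), source=str(path)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return SequenceDataset.from_records(records)


def write_fasta(dataset: SequenceDataset, path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at ``wrap`` columns."""
    bio = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "id": "id", "sequence": "sequence", "activity": "activity",
    "strength_label": "strength_label", "realness_label": "realness_label",
    "sigma_class": "sigma_class",
}


def read_activity_table(path: str | Path,
                        columns: Mapping[str, str] | None = None,
                        sep: str | None = None) -> SequenceDataset:
    """Read a delimited table (CSV/TSV, header row) of sequences with
    optional activity and label columns.

    ``columns`` maps record fields to column names in the file; only
    ``sequence`` is required.  Missing label columns become unknown, a
    missing activity column leaves activity absent.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    if cols["sequence"] not in df.columns:
        raise ValueError(
            f"{path}: missing sequence column {cols['sequence']!r} "
            f"(found {list(df.columns)})"
        )
    records = []
    for i, row in df.iterrows():
        ident = str(row[cols["id"]]) if cols["id"] in df.columns else f"row{i + 1}"
        activity = None
        if cols["activity"] in df.columns and pd.notna(row[cols["activity"]]):
            try:
                activity = float(row[cols["activity"]])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path} row {i + 1}: non-numeric activity "
                                 f"{row[cols['activity']]!r}") from exc
        kwargs: dict = {}
        for fname, enum_cls in (("strength_label", StrengthLabel),
                                ("realness_label", RealnessLabel),
                                ("sigma_class", SigmaClass)):
            if cols[fname] in df.columns and pd.notna(row[cols[fname]]):
                kwargs[fname] = enum_cls(str(row[cols[fname]]).lower())
        try:
            records.append(PromoterRecord(id=ident, sequence=str(row[cols["sequence"]]),
                                          activity=activity, source=str(path), **kwargs))
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 1}: {exc}") from exc
    return SequenceDataset.from_records(records)


def write_activity_table(dataset: SequenceDataset, path: str | Path) -> None:
    df = pd.DataFrame({
        "id": [r.id for r in dataset],
        "sequence": [r.sequence for r in dataset],
        "activity": [r.activity for r in dataset],
        "strength_label": [r.strength_label.value for r in dataset],
        "realness_label": [r.realness_label.value for r in dataset],
        "sigma_class": [r.sigma_class.value for r in dataset],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowing and extension
# ---------------------------------------------------------------------------

def window_to_50(record: PromoterRecord, start_offset: int = 11,
                 width: int = 50) -> PromoterRecord:
    """Cut a fixed window out of a longer promoter (1-based, closed).

    The default offset 11 takes characters 11-60 of an 81-mer: the 50 nt
    ending immediately upstream of the transcription start conventionally
    placed at position 61 in 81-bp promoter extracts.
    """
    if start_offset < 1:
        raise ValueError("start_offset is 1-based and must be >= 1")
    end = start_offset + width - 1
    if end > len(record):
        raise ValueError(
            f"window [{start_offset}, {end}] exceeds sequence length {len(record)}"
        )
    return replace(record, sequence=record.sequence[start_offset - 1:end])


def sample_windows(record: PromoterRecord, n: int, width: int = 50,
                   seed: int = 0) -> SequenceDataset:
    """Draw ``n`` random contiguous windows (uniform over valid starts)."""
    if width > len(record):
        raise ValueError(f"width {width} exceeds sequence length {len(record)}")
    rng = np.random.default_rng(seed)
    n_starts = len(record) - width + 1
    starts = rng.integers(0, n_starts, size=n)
    records = [
        replace(record, id=f"{record.id}_w{i}",
                sequence=record.sequence[s:s + width])
        for i, s in enumerate(starts)
    ]
    return SequenceDataset(records, fixed_length=width)


def extend_promoter(record: PromoterRecord, genome: SequenceDataset,
                    target_length: int) -> PromoterRecord:
    """Extend a promoter downstream to ``target_length`` using genomic
    context.  The record's sequence must occur exactly once, forward
    strand, across the genome dataset."""
    if target_length < len(record):
        raise ValueError("target_length must be >= current length")
    if target_length == len(record):
        return record
    hits: list[tuple[str, int]] = []
    for chrom in genome:
        start = chrom.sequence.find(record.sequence)
        while start != -1:
            hits.append((chrom.id, start))
            start = chrom.sequence.find(record.sequence, start + 1)
    if len(hits) != 1:
        raise ValueError(
            f"record {record.id!r}: expected exactly one genomic match, found {len(hits)}"
        )
    chrom_id, start = hits[0]
    chrom = next(c for c in genome if c.id == chrom_id)
    end = start + target_length
    if end > len(chrom):
        raise ValueError(
            f"extension to {target_length} bp runs off the end of {chrom_id!r}"
        )
    return replace(record, sequence=chrom.sequence[start:end])


# ---------------------------------------------------------------------------
# Activity
# ---------------------------------------------------------------------------

def normalize_activity(fi: float, od600: float) -> float:
    """Promoter activity = fluorescence intensity / OD600."""
    if od600 <= 0:
        raise ValueError(f"od600 must be > 0, got {od600}")
    if fi < 0:
        raise ValueError(f"fluorescence intensity must be >= 0, got {fi}")
    return fi / od600


def call_active(activity: float, negative_control_activity: float,
                fold: float = 1.2) -> ActivityCall:
    """Call a promoter active if its activity exceeds the negative control
    by more than 20% (strictly above ``fold`` x control)."""
    if negative_control_activity <= 0:
        raise ValueError("negative control activity must be > 0")
    return (ActivityCall.ACTIVE if activity > fold * negative_control_activity
            else ActivityCall.INACTIVE)
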
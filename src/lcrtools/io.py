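"""Proteome and annotation input/output, and the coordinate model shared by all modules.

All sequence coordinates exposed to users (tables, reports, CLI output) are
1-based inclusive, the convention used to write residue ranges such as
``K223-P234``.  Internal computations use 0-based half-open intervals; the
:class:`SequenceInterval` type is the boundary between the two worlds.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "Proteome",
    "AnnotationSet",
    "SequenceInterval",
    "read_proteome",
    "write_proteome",
    "read_annotation",
    "write_lcr_table",
    "read_lcr_table",
    "LCR_TABLE_COLUMNS",
]

LCR_TABLE_COLUMNS = [
    "protein_id",
    "lcr_index",
    "start",
    "stop",
    "length",
    "sequence",
    "type_id",
    "type_copy_number",
    "entropy_bits",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence from a proteome.

    ``protein_id`` is the first whitespace-delimited token of the FASTA
    header; ``sequence`` is uppercase with any trailing stop ``*`` removed.
    """

    protein_id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"sequence of {self.protein_id!r} contains whitespace")

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome:
    """Ordered collection of :class:`ProteinRecord` with unique ids.

    Iteration order is input (file) order and stable, which matters for the
    concatenation-based random sequence sampling.
    """

    def __init__(self, records: Iterable[ProteinRecord], name: str = "proteome"):
        self.records: list[ProteinRecord] = list(records)
        self.name = name
        self._index: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.protein_id in self._index:
                raise ValueError(f"duplicate protein id {rec.protein_id!r}")
            self._index[rec.protein_id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, key: str | int) -> ProteinRecord:
        if isinstance(key, int):
            return self.records[key]
        return self.records[self._index[key]]

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    @property
    def lengths(self) -> list[int]:
        return [len(r) for r in self.records]

    def __repr__(self) -> str:
        return f"Proteome({self.name!r}, n={len(self)}, total_length={self.total_length})"


@dataclass(frozen=True)
class AnnotationSet:
    """Named set of protein ids, e.g. proteins annotated to the nucleolus."""

    name: str
    protein_ids: frozenset[str]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.protein_ids

    def __len__(self) -> int:
        return len(self.protein_ids)


@dataclass(frozen=True, order=True)
class SequenceInterval:
    """Residue range on one protein, 1-based inclusive on both ends."""

    protein_id: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"invalid interval {self.start}..{self.stop} on {self.protein_id!r}"
            )

    def __len__(self) -> int:
        return self.stop - self.start + 1

    @property
    def slice(self) -> slice:
        """0-based half-open slice of the protein sequence."""
        return slice(self.start - 1, self.stop)

    @classmethod
    def from_zero_based(cls, protein_id: str, start0: int, stop0: int) -> "SequenceInterval":
        """Build from a 0-based half-open [start0, stop0) range."""
        return cls(protein_id, start0 + 1, stop0)

    def overlaps(self, other: "SequenceInterval") -> bool:
        return (
            self.protein_id == other.protein_id
            and self.start <= other.stop
            and other.start <= self.stop
        )


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _accession_from_id(protein_id: str) -> str:
    # UniProt convention: db|ACCESSION|ENTRY_NAME
    parts = protein_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return protein_id


def read_proteome(
    path: str | Path,
    name: str | None = None,
    extract_accession: bool = False,
) -> Proteome:
    """Read a (optionally gzipped) multi-record FASTA file into a Proteome.

    Sequences are uppercased and a trailing ``*`` stop character is stripped.
    With ``extract_accession=True``, UniProt-style ``db|ACC|NAME`` ids are
    reduced to the accession between the pipes.

    Raises ``ValueError`` for an empty file or duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            pid = rec.id
            if extract_accession:
                pid = _accession_from_id(pid)
            records.append(ProteinRecord(pid, rec.description, seq))
    if not records:
        raise ValueError(f"no records in {path}")
    if name is None:
        name = path.name
        for suffix in (".gz", ".fasta", ".fa", ".faa"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
    return Proteome(records, name=name)


def write_proteome(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    """Write a proteome as plain FASTA, preserving record order."""
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in proteome:
            header = rec.description if rec.description else rec.protein_id
            if not header.startswith(rec.protein_id):
                header = rec.protein_id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_annotation(
    path: str | Path,
    proteome: Proteome,
    name: str | None = None,
    extract_accession: bool = False,
) -> AnnotationSet:
    """Read an annotation FASTA (a subset of the proteome) into an AnnotationSet.

    Ids present in the file but absent from ``proteome`` are dropped; the
    number dropped is recorded on the returned object's ``name`` log via the
    module logger.  If no id overlaps the proteome, raises ``ValueError``.
    """
    import logging

    path = Path(path)
    if name is None:
        name = path.stem
    seen: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid = _accession_from_id(rec.id) if extract_accession else rec.id
            seen.append(pid)
    kept = {pid for pid in seen if pid in proteome}
    dropped = len(set(seen)) - len(kept)
    if not kept:
        raise ValueError(
            f"annotation {name!r} does not match proteome {proteome.name!r}: "
            f"none of {len(set(seen))} ids found"
        )
    if dropped:
        logging.getLogger(__name__).info(
            "annotation %s: %d ids not in proteome %s were dropped",
            name, dropped, proteome.name,
        )
    return AnnotationSet(name=name, protein_ids=frozenset(kept))


def write_lcr_table(calls, path: str | Path) -> None:
    """Write LCR calls as a TSV table (1-based inclusive coordinates).

    Calls must be grouped by protein (each protein's calls contiguous, in
    proteome order) and sorted by start, non-overlapping, within each
    protein; all three are verified.
    """
    rows = []
    finished: set[str] = set()
    prev_pid: str | None = None
    prev_stop = 0
    for call in calls:
        iv = call.interval
        if iv.protein_id != prev_pid:
            if iv.protein_id in finished:
                raise ValueError(
                    f"calls for {iv.protein_id!r} are not contiguous; "
                    "group and sort calls per protein"
                )
            if prev_pid is not None:
                finished.add(prev_pid)
            prev_pid, prev_stop = iv.protein_id, 0
        if iv.start <= prev_stop:
            raise ValueError(
                f"overlapping or unsorted LCR intervals on {iv.protein_id!r} "
                f"at {iv.start}"
            )
        prev_stop = iv.stop
        rows.append(
            {
                "protein_id": iv.protein_id,
                "lcr_index": call.lcr_index,
                "start": iv.start,
                "stop": iv.stop,
                "length": len(iv),
                "sequence": call.sequence,
                "type_id": call.type_id if call.type_id is not None else "",
                "type_copy_number": call.type_copy_number
                if call.type_copy_number is not None
                else "",
                "entropy_bits": f"{call.entropy_bits:.6f}"
                if call.entropy_bits is not None
                else "",
            }
        )
    df = pd.DataFrame(rows, columns=LCR_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_lcr_table(path: str | Path):
    """Read back a TSV written by :func:`write_lcr_table` as a list of LcrCall."""
    from .calling import LcrCall  # deferred: calling depends on this module

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sequence": str})
    calls = []
    for row in df.itertuples(index=False):
        iv = SequenceInterval(row.protein_id, int(row.start), int(row.stop))
        calls.append(
            LcrCall(
                interval=iv,
                sequence=row.sequence,
                lcr_index=int(row.lcr_index),
                type_id=int(row.type_id) if pd.notna(row.type_id) else None,
                type_copy_number=int(row.type_copy_number)
                if pd.notna(row.type_copy_number)
                else None,
                entropy_bits=float(row.entropy_bits)
                if pd.notna(row.entropy_bits)
                else None,
            )
        )
    return calls
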
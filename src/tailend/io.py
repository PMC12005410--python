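"""Readers and writers for the formats the tool touches.

Sequences are stored in the DNA alphabet: U is converted to T on ingest and
everything is case-folded to upper case.  Reads from U-tailed libraries
therefore carry T tails, which is also what a sequencer reports for the
cDNA of a U-tail.

Count tables are plain TSV with columns ``target_id, position, base, count``;
floats are serialized with six significant digits.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SeqRecord",
    "CountTable",
    "ParseError",
    "read_fasta",
    "read_fastq",
    "write_fastq",
    "read_count_table",
    "write_count_table",
    "read_config",
]

_RNA2DNA = str.maketrans("Uu", "Tt")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ/TSV input."""


@dataclass(frozen=True)
class SeqRecord:
    """A single sequence record in DNA alphabet.

    ``quality``, when present, is the raw FASTQ quality string; it is carried
    through but never interpreted downstream.
    """

    id: str
    bases: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ParseError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


def _normalize(seq: str) -> str:
    return seq.translate(_RNA2DNA).upper()


def read_fasta(path: Union[str, Path]) -> List[SeqRecord]:
    """Read a FASTA file into a list of records (U->T, upper-cased)."""
    path = Path(path)
    records = []
    with _maybe_gzip(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fasta"):
                records.append(SeqRecord(id=rec.id, bases=_normalize(str(rec.seq))))
        except ValueError as exc:  # Biopython's parse error
            raise ParseError(f"{path}: {exc}") from exc
    return records


def _maybe_gzip(path: Path) -> _io.TextIOBase:
    """Open plain or gzip text transparently, detected by magic bytes."""
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: Union[str, Path]) -> Iterator[SeqRecord]:
    """Lazily yield records from a FASTQ file (plain or gzip).

    Raises :class:`ParseError` naming the offending record for truncated
    files or base/quality length mismatches.
    """
    path = Path(path)
    handle = _maybe_gzip(path)
    title = "<none>"
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            rec_id = title.split(None, 1)[0]
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {rec_id!r}: sequence/quality length mismatch"
                )
            yield SeqRecord(id=rec_id, bases=_normalize(seq), quality=qual)
    except ValueError as exc:
        raise ParseError(f"{path}: near record {title!r}: {exc}") from exc
    finally:
        handle.close()


def write_fastq(records: Iterable[SeqRecord], path: Union[str, Path]) -> int:
    """Write records as FASTQ; gzip output iff the path ends in ``.gz``.

    Records without quality get a constant 'I' quality string.  Returns the
    number of records written.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.bases)
            out.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Count tables


@dataclass
class CountTable:
    """Per-position counts for one target.

    ``rows`` is an ordered list of ``(position, base, count)`` with strictly
    increasing 1-based positions; ``total`` must equal the sum of counts.
    """

    target_id: str
    rows: List[Tuple[int, str, float]] = field(default_factory=list)
    total: float = 0.0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("count table must be non-empty")
        positions = [p for p, _, _ in self.rows]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValueError("positions must be strictly increasing")
        for p, _, c in self.rows:
            if p < 1:
                raise ValueError(f"position {p} is not 1-based")
            if c < 0:
                raise ValueError(f"negative count at position {p}")
        s = sum(c for _, _, c in self.rows)
        if abs(s - self.total) > 1e-6 * max(1.0, abs(self.total)):
            raise ValueError(f"total {self.total} != sum of counts {s}")

    @classmethod
    def from_counts(cls, target_id: str, counts: dict, target_bases: str = "") -> "CountTable":
        rows = []
        for p in sorted(counts):
            base = target_bases[p - 1] if target_bases else "N"
            rows.append((p, base, counts[p]))
        return cls(target_id=target_id, rows=rows, total=sum(counts.values()))

    @property
    def counts(self) -> dict:
        return {p: c for p, _, c in self.rows}


def _fmt(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.6g}"


def write_count_table(table: CountTable, path: Union[str, Path]) -> None:
    with open(path, "wt") as out:
        out.write("target_id\tposition\tbase\tcount\n")
        for p, base, c in table.rows:
            out.write(f"{table.target_id}\t{p}\t{base}\t{_fmt(c)}\n")


def read_count_table(path: Union[str, Path]) -> CountTable:
    path = Path(path)
    with open(path, "rt") as handle:
        header = handle.readline().rstrip("\n").split("\t")
        expected = ["target_id", "position", "base", "count"]
        if header[:4] != expected:
            raise ParseError(f"{path}: expected header {expected}, got {header}")
        target_id = None
        rows: List[Tuple[int, str, float]] = []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            tid, pos, base, count = fields[:4]
            if target_id is None:
                target_id = tid
            elif tid != target_id:
                raise ParseError(f"{path}:{lineno}: mixed target ids in one table")
            try:
                rows.append((int(pos), base, float(count)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if target_id is None:
        raise ParseError(f"{path}: empty count table")
    return CountTable(target_id=target_id, rows=rows, total=sum(c for _, _, c in rows))


# ---------------------------------------------------------------------------
# Run configuration

def read_config(path: Union[str, Path]) -> dict:
    """Parse a plain ``key = value`` config file ('#' starts a comment)."""
    cfg = {}
    with open(path, "rt") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg
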
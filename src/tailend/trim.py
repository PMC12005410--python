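"""Detection and removal of 3' homonucleotide tails and ligated adapters.

A tailed read is cut at the first stretch of ``run_len`` consecutive tail
bases that is followed by at least ``lookahead`` further bases of which at
least ``min_matches`` are the tail base.  The lookahead window must exist in
full: a read that ends in exactly ``run_len`` tail bases is *unselected*,
which is what produces the small selection loss seen in real libraries.

Adapter-ligated reads are cut 5' of the first exact occurrence of a short
adapter seed (error rate 0); no alignment is attempted.

N bases never count as tail-base or seed matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io import SeqRecord

__all__ = [
    "TailSpec",
    "AdapterSpec",
    "TrimOutcome",
    "SelectionStats",
    "find_tail_start",
    "trim_tailed_read",
    "trim_adapter_read",
    "selection_stats",
]

SELECTED = "selected"
UNSELECTED = "unselected"
TOO_SHORT = "too_short"


@dataclass(frozen=True)
class TailSpec:
    """Signature of a 3' homonucleotide tail.

    Defaults encode the published selection criterion: a run of five tail
    bases plus at least three tail bases within the next four positions.
    """

    tail_base: str
    run_len: int = 5
    lookahead: int = 4
    min_matches: int = 3
    min_retained_len: int = 4

    def __post_init__(self) -> None:
        if self.tail_base not in "ACGT":
            raise ValueError(f"tail base must be one of A,C,G,T, got {self.tail_base!r}")
        if self.run_len < 1 or self.min_retained_len < 1:
            raise ValueError("run_len and min_retained_len must be >= 1")
        if self.min_matches > self.lookahead:
            raise ValueError("min_matches must not exceed lookahead")


@dataclass(frozen=True)
class AdapterSpec:
    """Exact-match seed of a ligated 3' adapter (default: Illumina read-through)."""

    seed: str = "AGATCGG"
    min_retained_len: int = 4

    def __post_init__(self) -> None:
        if len(self.seed) < 4:
            raise ValueError("adapter seed must be at least 4 nt")


@dataclass(frozen=True)
class TrimOutcome:
    """Result of trimming one read.

    ``cut_position`` is the 1-based index of the first removed base;
    ``trimmed_bases`` is present only for selected reads and is always a
    prefix of the input read.
    """

    status: str
    trimmed_bases: Optional[str] = None
    cut_position: Optional[int] = None


def find_tail_start(bases: str, spec: TailSpec) -> Optional[int]:
    """Return the 1-based position of the first tail-signature hit, or None.

    The hit is the smallest p such that ``bases[p .. p+run_len-1]`` are all
    the tail base and the following ``lookahead`` bases exist and contain at
    least ``min_matches`` tail bases.
    """
    t = spec.tail_base
    n = len(bases)
    last_start = n - (spec.run_len + spec.lookahead)  # 0-based, inclusive
    i = 0
    while i <= last_start:
        if bases[i] != t:
            i += 1
            continue
        run = bases[i : i + spec.run_len]
        if run != t * spec.run_len:
            i += 1
            continue
        window = bases[i + spec.run_len : i + spec.run_len + spec.lookahead]
        if sum(1 for b in window if b == t) >= spec.min_matches:
            return i + 1
        i += 1
    return None


def trim_tailed_read(record: SeqRecord, spec: TailSpec) -> TrimOutcome:
    p = find_tail_start(record.bases, spec)
    if p is None:
        return TrimOutcome(status=UNSELECTED)
    retained = record.bases[: p - 1]
    if len(retained) < spec.min_retained_len:
        return TrimOutcome(status=TOO_SHORT)
    return TrimOutcome(status=SELECTED, trimmed_bases=retained, cut_position=p)


def trim_adapter_read(record: SeqRecord, spec: AdapterSpec) -> TrimOutcome:
    idx = record.bases.find(spec.seed)
    if idx < 0:
        return TrimOutcome(status=UNSELECTED)
    retained = record.bases[:idx]
    if len(retained) < spec.min_retained_len:
        return TrimOutcome(status=TOO_SHORT)
    return TrimOutcome(status=SELECTED, trimmed_bases=retained, cut_position=idx + 1)


@dataclass
class SelectionStats:
    total_reads: int
    selected: int
    too_short: int
    unselected: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("selection stats require at least one read")
        if self.selected + self.too_short + self.unselected != self.total_reads:
            raise ValueError("status counts do not add up to total reads")

    @property
    def pct_selected(self) -> float:
        return 100.0 * self.selected / self.total_reads

    def __str__(self) -> str:
        return (
            f"{self.total_reads} reads: {self.selected} selected "
            f"({self.pct_selected:.1f}%), {self.too_short} too short, "
            f"{self.unselected} unselected"
        )


def selection_stats(outcomes: Iterable[TrimOutcome]) -> SelectionStats:
    counts = {SELECTED: 0, TOO_SHORT: 0, UNSELECTED: 0}
    total = 0
    for outcome in outcomes:
        counts[outcome.status] += 1
        total += 1
    if total == 0:
        raise ValueError("no trim outcomes supplied")
    return SelectionStats(
        total_reads=total,
        selected=counts[SELECTED],
        too_short=counts[TOO_SHORT],
        unselected=counts[UNSELECTED],
    )
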
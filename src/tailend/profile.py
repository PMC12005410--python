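"""Anchored exact mapping of trimmed reads and 3'-end profile aggregation.

Two target regimes:

* **short** targets (< 40 nt, e.g. 6S-1 pRNAs): a trimmed read is accepted
  iff it is an exact prefix of the target of length >= 5; because all pRNA
  length variants share one 5' end, the 3'-end position equals the trimmed
  read length.
* **long** targets (3'-fragments of larger RNAs): the first 30 nt of the
  3'-proximal 40-nt window serve as a mismatch-free anchor; an accepted read
  contains the anchor exactly once, matches the target at every base 3' of
  it, and ends at one of the last 11 target positions [L-10, L].

Profiles store raw per-position counts and the per-mille normalization
f1000[p] = 1000 * counts[p] / total_mapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional

__all__ = [
    "TargetSeq",
    "EndProfile",
    "MappingReport",
    "map_read_short",
    "map_read_long",
    "build_profile",
    "length_histogram",
]


@dataclass(frozen=True)
class TargetSeq:
    """A reference sequence against which 3'-ends are profiled.

    The mode is implied by length: targets shorter than ``window_len`` use
    the 5'-prefix criterion (short mode), longer ones the 3'-window anchor.
    """

    id: str
    bases: str
    anchor_5p_len: int = 5
    window_len: int = 40
    anchor_len: int = 30

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty target sequence")
        if self.anchor_len >= self.window_len:
            raise ValueError("anchor_len must be smaller than window_len")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mode(self) -> str:
        return "short" if len(self.bases) < self.window_len else "long"

    @property
    def anchor(self) -> str:
        """The 30-nt mismatch-free anchor of a long target."""
        if self.mode != "long":
            raise ValueError("anchor is defined for long targets only")
        L = len(self.bases)
        return self.bases[L - self.window_len + 1 - 1 : L - (self.window_len - self.anchor_len)]

    @property
    def end_window(self) -> range:
        """Target coordinates at which an accepted long-mode read may end."""
        L = len(self.bases)
        return range(L - (self.window_len - self.anchor_len), L + 1)


def map_read_short(trimmed_bases: str, target: TargetSeq) -> Optional[int]:
    """Map a trimmed read to a short target; returns its 3'-end position.

    Accepted iff the read is an exact target prefix of length >=
    ``anchor_5p_len``; the returned position equals the read length.
    """
    if target.mode != "short":
        raise ValueError(f"target {target.id} is not in short mode")
    n = len(trimmed_bases)
    if n < target.anchor_5p_len or n > len(target.bases):
        return None
    if target.bases[:n] != trimmed_bases:
        return None
    return n


def map_read_long(trimmed_bases: str, target: TargetSeq) -> Optional[int]:
    """Map a trimmed read to a long target; returns its 3'-end position.

    Requires a unique exact occurrence of the 30-nt anchor, exact agreement
    with the target 3' of the anchor, and an end within the last 11 target
    positions.  A read whose anchor occurs twice raises ``AmbiguousAnchor``.
    """
    if target.mode != "long":
        raise ValueError(f"target {target.id} is not in long mode")
    anchor = target.anchor
    idx = trimmed_bases.find(anchor)
    if idx < 0:
        return None
    if trimmed_bases.find(anchor, idx + 1) >= 0:
        raise AmbiguousAnchor(target.id)
    L = len(target.bases)
    anchor_end = L - (target.window_len - target.anchor_len)  # target coord of anchor's last base
    tail = trimmed_bases[idx + len(anchor) :]
    end_pos = anchor_end + len(tail)
    if end_pos > L:
        return None  # read runs past the target 3' end
    if tail and target.bases[anchor_end : anchor_end + len(tail)] != tail:
        return None
    return end_pos


class AmbiguousAnchor(ValueError):
    """The 30-nt anchor occurs more than once in a read."""


@dataclass
class MappingReport:
    input_reads: int = 0
    accepted: int = 0
    rejected: int = 0
    ambiguous_anchor: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {
            "input_reads": self.input_reads,
            "accepted": self.accepted,
            "rejected": self.rejected,
            "ambiguous_anchor": self.ambiguous_anchor,
        }


@dataclass
class EndProfile:
    """Per-position raw 3'-end counts and f1000 fractions for one library."""

    target_id: str
    library_label: str
    counts: Dict[int, float]
    total_mapped: float
    tail_base: Optional[str] = None
    report: MappingReport = field(default_factory=MappingReport)

    def __post_init__(self) -> None:
        if self.total_mapped <= 0:
            raise ValueError("empty profile: no mapped reads")
        s = sum(self.counts.values())
        if abs(s - self.total_mapped) > 1e-6 * self.total_mapped:
            raise ValueError(
                f"total_mapped {self.total_mapped} != sum of counts {s}"
            )

    @property
    def f1000(self) -> Dict[int, float]:
        return {p: 1000.0 * c / self.total_mapped for p, c in self.counts.items()}

    def f1000_at(self, position: int) -> float:
        return 1000.0 * self.counts.get(position, 0.0) / self.total_mapped


def build_profile(
    trimmed_reads: Iterable[str],
    target: TargetSeq,
    library_label: str,
    tail_base: Optional[str] = None,
) -> EndProfile:
    """Aggregate accepted 3'-end positions of trimmed reads into a profile.

    Raises ``ValueError`` if no read maps (empty profiles are meaningless).
    """
    mapper = map_read_short if target.mode == "short" else map_read_long
    counts: Counter = Counter()
    report = MappingReport()
    for bases in trimmed_reads:
        report.input_reads += 1
        try:
            pos = mapper(bases, target)
        except AmbiguousAnchor:
            report.ambiguous_anchor += 1
            continue
        if pos is None:
            report.rejected += 1
        else:
            counts[pos] += 1
            report.accepted += 1
    if report.accepted == 0:
        raise ValueError(f"empty profile: no reads mapped to target {target.id}")
    return EndProfile(
        target_id=target.id,
        library_label=library_label,
        counts=dict(counts),
        total_mapped=float(report.accepted),
        tail_base=tail_base,
        report=report,
    )


def length_histogram(trimmed_reads: Iterable[str]) -> Dict[int, int]:
    """Histogram of trimmed read lengths (no mapping involved)."""
    return dict(Counter(len(r) for r in trimmed_reads))
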
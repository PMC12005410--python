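"""Synthetic FASTQ libraries with known ground truth.

Each read is a 5' fragment of the target ending at a position drawn from a
programmed true 3'-end distribution, followed by a homonucleotide tail (or
a ligated-adapter read-through), cut or padded to the read length (default
75 nt, the paper-scale single-end read length).  Padding continues the tail
base for tailed chemistry - emulating the homopolymer stretch encoded in
the RT primer - and a fixed downstream base for adapter chemistry.

All randomness comes from one seeded ``numpy.random.default_rng``; draws
are consumed in a fixed, documented order (all end positions first, then
per-read tail lengths, then substitution errors read by read), so a given
seed yields byte-identical FASTQ on any platform.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .io import SeqRecord
from .merge import annotate_ambiguity, collapse_distribution
from .profile import TargetSeq

__all__ = ["TailLenDist", "SynthSpec", "generate_library", "truth_collapsed_profile"]

#: read-through of the TruSeq indexed adapter as it appears in a sense read
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TailLenDist:
    """Tail-length distribution: ``fixed(k)``, ``uniform(lo, hi)`` (inclusive)
    or ``geometric(p)`` shifted by a minimum length."""

    kind: str
    a: float
    b: float = 0.0

    @classmethod
    def fixed(cls, k: int) -> "TailLenDist":
        return cls("fixed", k)

    @classmethod
    def uniform(cls, lo: int, hi: int) -> "TailLenDist":
        if lo > hi:
            raise ValueError("uniform tail-length bounds out of order")
        return cls("uniform", lo, hi)

    @classmethod
    def geometric(cls, p: float, minimum: int = 1) -> "TailLenDist":
        if not 0 < p <= 1:
            raise ValueError("geometric parameter must be in (0, 1]")
        return cls("geometric", p, minimum)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, int(self.a), dtype=np.int64)
        if self.kind == "uniform":
            return rng.integers(int(self.a), int(self.b) + 1, size=n)
        if self.kind == "geometric":
            return rng.geometric(self.a, size=n) - 1 + int(self.b)
        raise ValueError(f"unknown tail length distribution {self.kind!r}")

    @property
    def max_possible(self) -> float:
        if self.kind == "fixed":
            return self.a
        if self.kind == "uniform":
            return self.b
        return float("inf")

    @classmethod
    def parse(cls, text: str) -> "TailLenDist":
        """Parse CLI syntax: ``fixed:12``, ``uniform:10,25``, ``geometric:0.2,9``."""
        kind, _, rest = text.partition(":")
        parts = [float(x) for x in rest.split(",")] if rest else []
        if kind == "fixed":
            return cls.fixed(int(parts[0]))
        if kind == "uniform":
            return cls.uniform(int(parts[0]), int(parts[1]))
        if kind == "geometric":
            return cls.geometric(parts[0], int(parts[1]) if len(parts) > 1 else 1)
        raise ValueError(f"cannot parse tail length distribution {text!r}")


@dataclass
class SynthSpec:
    """Full recipe for one synthetic library.

    The default tail-length distribution, uniform on [10, 25] nt, sits in
    the tail-length range seen on tailing gels while always carrying the
    five-plus-lookahead selection signature, so the default library is 100%
    selectable; ``error_rate`` is 0 by default (error-free reads).
    """

    target: TargetSeq
    true_end_dist: Dict[int, float]
    n_reads: int
    chemistry: str = "tail"  # "tail" or "adapter"
    tail_base: Optional[str] = None
    tail_len_dist: TailLenDist = field(default_factory=lambda: TailLenDist.uniform(10, 25))
    adapter_seq: str = DEFAULT_ADAPTER
    read_len: int = 75
    error_rate: float = 0.0
    start_position: Optional[int] = None  # long targets: fixed 5' start (default: anchor start)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if self.chemistry not in ("tail", "adapter"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.chemistry == "tail" and self.tail_base not in ("A", "C", "G", "T"):
            raise ValueError("tailed chemistry requires tail_base in {A,C,G,T}")
        total = sum(self.true_end_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"true end distribution sums to {total}, not 1")
        n = len(self.target.bases)
        for pos in self.true_end_dist:
            if not 1 <= pos <= n:
                raise ValueError(f"end position {pos} outside target (1..{n})")
        if (
            self.chemistry == "tail"
            and self.tail_len_dist.max_possible < 9
        ):
            _warnings.warn(
                "all tail lengths are below run_len + lookahead (9); "
                "no synthetic read will carry the selection signature",
                stacklevel=2,
            )


def _fragment(spec: SynthSpec, end: int) -> str:
    if spec.target.mode == "short":
        return spec.target.bases[:end]
    start = spec.start_position
    if start is None:
        start = len(spec.target.bases) - spec.target.window_len + 1  # covers the anchor
    if end < start:
        raise ValueError(f"end position {end} upstream of read start {start}")
    return spec.target.bases[start - 1 : end]


def generate_library(spec: SynthSpec) -> Tuple[List[SeqRecord], Dict[int, int]]:
    """Generate the synthetic library; returns (records, truth record).

    The truth record maps each drawn 3'-end position to its realized read
    count.  Deterministic for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.array(sorted(spec.true_end_dist), dtype=np.int64)
    probs = np.array([spec.true_end_dist[int(p)] for p in positions], dtype=float)
    probs = probs / probs.sum()
    # draw order: 1) end positions, 2) tail lengths, 3) errors per read
    ends = rng.choice(positions, size=spec.n_reads, p=probs)
    if spec.chemistry == "tail":
        tail_lens = spec.tail_len_dist.draw(rng, spec.n_reads)
    else:
        tail_lens = np.zeros(spec.n_reads, dtype=np.int64)

    records: List[SeqRecord] = []
    truth: Dict[int, int] = {}
    for i in range(spec.n_reads):
        end = int(ends[i])
        truth[end] = truth.get(end, 0) + 1
        frag = _fragment(spec, end)
        if spec.chemistry == "tail":
            suffix = spec.tail_base * int(tail_lens[i])
            pad_char = spec.tail_base
        else:
            suffix = spec.adapter_seq
            pad_char = "A"
        read = (frag + suffix)[: spec.read_len]
        if len(read) < spec.read_len:
            read = read + pad_char * (spec.read_len - len(read))
        if spec.error_rate > 0.0:
            read = _mutate(read, spec.error_rate, rng)
        records.append(
            SeqRecord(id=f"synth_{i}", bases=read, quality="I" * len(read))
        )
    return records, truth


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(read)) < rate)[0]
    if hits.size == 0:
        return read
    chars = list(read)
    for j in hits:
        choices = [b for b in "ACGT" if b != chars[j]]
        chars[j] = choices[rng.integers(0, 3)]
    return "".join(chars)


def truth_collapsed_profile(spec: SynthSpec, truth: Dict[int, int]) -> Dict[int, int]:
    """Expected trimmed-and-profiled counts for the realized end positions.

    For tailed chemistry this is the analytic collapse of the truth record
    onto window anchors; for adapter chemistry the truth passes through
    unchanged (no blind spots).
    """
    if spec.chemistry == "adapter":
        return dict(truth)
    amap = annotate_ambiguity(spec.target, spec.tail_base)
    collapsed = collapse_distribution({p: float(c) for p, c in truth.items()}, amap)
    return {p: int(round(c)) for p, c in collapsed.items()}
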
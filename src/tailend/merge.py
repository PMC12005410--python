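"""Merging two differently-tailed 3'-end profiles into one resolved distribution.

Homonucleotide tailing makes a read's 3' end invisible wherever the target
continues with the tailing base: all reads ending inside a maximal run of
the tail base (or at the non-tail *anchor* position immediately 5' of it)
are trimmed back to the anchor and counted there.  Two libraries tailed
with different bases are blind at different positions, so their per-mille
profiles (f1000) can be combined into a fully resolved distribution.

The merge iterates over the target 3' -> 5' and classifies each position:

* **case #1** - base differs from both tail bases: merged value is the mean
  of the two libraries.
* **case #2** - a run of one library's tail base whose anchor is the other
  library's tail base: the run takes the resolving library's values
  verbatim (single-source); the collapsed library's estimate at the anchor
  is its anchor mass minus the resolved run mass, consumed by the next
  window 5' of it.
* **case #3** - that subtraction goes negative: the libraries are
  incongruent; the tail-base anchor is clamped to 0, the run receives the
  mean of the two competing window totals, and a warning is emitted.
* **case #4** - a run whose anchor is a non-tail base in both libraries:
  the collapsed library's window mass is distributed over the window with a
  scaling factor SF = total_collapsed / total_resolved and the merged value
  is the per-position mean of the two library estimates.

Per-position error bars are the two-estimate sample standard deviation
|x - y| / sqrt(2); single-source positions carry sd 0 with a flag.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .profile import EndProfile, TargetSeq

__all__ = [
    "AmbiguityMap",
    "Window",
    "MergeResult",
    "PositionResult",
    "annotate_ambiguity",
    "merge_two_libraries",
    "merged_read_counts",
    "position_sd",
    "collapse_distribution",
]

DIRECT = "direct"
ANCHOR = "anchor"
TRIMMED = "trimmed"
UNRESOLVABLE = "unresolvable"


@dataclass(frozen=True)
class Window:
    """A maximal run ``[run_start .. run_end]`` of the tail base plus its
    anchor (the position immediately 5' of the run; 0 if the run starts at
    the target 5' terminus, in which case the run is unresolvable)."""

    anchor: int
    run_start: int
    run_end: int

    @property
    def run(self) -> range:
        return range(self.run_start, self.run_end + 1)


@dataclass
class AmbiguityMap:
    """Per-position classification induced by one tail base on one target."""

    target_id: str
    tail_base: str
    classification: Dict[int, str]
    windows: List[Window]

    def window_at(self, position: int) -> Optional[Window]:
        for w in self.windows:
            if w.run_start <= position <= w.run_end:
                return w
        return None


def annotate_ambiguity(target: TargetSeq, tail_base: str) -> AmbiguityMap:
    """Classify every target position as direct / anchor / trimmed / unresolvable
    with respect to one tailing base."""
    if tail_base not in "ACGT":
        raise ValueError(f"tail base must be one of A,C,G,T, got {tail_base!r}")
    bases = target.bases
    n = len(bases)
    classification = {p: DIRECT for p in range(1, n + 1)}
    windows: List[Window] = []
    p = 1
    while p <= n:
        if bases[p - 1] != tail_base:
            p += 1
            continue
        start = p
        while p <= n and bases[p - 1] == tail_base:
            p += 1
        end = p - 1
        anchor = start - 1
        windows.append(Window(anchor=anchor, run_start=start, run_end=end))
        for q in range(start, end + 1):
            classification[q] = TRIMMED if anchor > 0 else UNRESOLVABLE
        if anchor > 0:
            classification[anchor] = ANCHOR
    return AmbiguityMap(
        target_id=target.id,
        tail_base=tail_base,
        classification=classification,
        windows=windows,
    )


def position_sd(estimate_x: float, estimate_y: float) -> float:
    """Two-estimate sample standard deviation, |x - y| / sqrt(2)."""
    return abs(estimate_x - estimate_y) / math.sqrt(2.0)


@dataclass
class PositionResult:
    position: int
    base: str
    merged_f1000: float
    case_label: str
    estimate_x: Optional[float] = None
    estimate_y: Optional[float] = None
    sd: float = 0.0
    flags: Tuple[str, ...] = ()


@dataclass
class MergeResult:
    """Resolved per-position distribution from two differently-tailed libraries."""

    target_id: str
    label_x: str
    label_y: str
    tail_x: str
    tail_y: str
    positions: Dict[int, PositionResult]
    warnings: List[str]
    merged_total: float

    @property
    def merged_f1000(self) -> Dict[int, float]:
        return {p: r.merged_f1000 for p, r in self.positions.items()}

    @property
    def case_labels(self) -> Dict[int, str]:
        return {p: r.case_label for p, r in self.positions.items()}

    @property
    def merged_counts(self) -> Dict[int, float]:
        return merged_read_counts(self)

    def nonzero(self) -> Dict[int, float]:
        return {p: v for p, v in self.merged_f1000.items() if v > 0}


def merged_read_counts(result: MergeResult) -> Dict[int, float]:
    """Merged absolute counts: f1000 / 1000 x mean of the two library totals."""
    return {
        p: r.merged_f1000 / 1000.0 * result.merged_total
        for p, r in result.positions.items()
    }


def _mean(x: float, y: float) -> float:
    return (x + y) / 2.0


def merge_two_libraries(
    profile_x: EndProfile,
    profile_y: EndProfile,
    target: TargetSeq,
    log=None,
) -> MergeResult:
    """Merge two profiles with different tail bases; see module docstring.

    ``profile_x``/``profile_y`` must be tailed profiles on the same target
    with distinct tail bases.  Incongruency warnings (case #3) are appended
    to ``result.warnings`` and written to ``log`` (default: stderr).
    """
    if profile_x.target_id != profile_y.target_id:
        raise ValueError("profiles are on different targets")
    if profile_x.target_id != target.id:
        raise ValueError("target does not match the profiles")
    tail_x, tail_y = profile_x.tail_base, profile_y.tail_base
    if tail_x is None or tail_y is None:
        raise ValueError("both profiles must declare a tail base")
    if tail_x == tail_y:
        raise ValueError("identical tail bases cannot be merged")
    n = len(target.bases)
    for prof, tb in ((profile_x, tail_x), (profile_y, tail_y)):
        for p, c in prof.counts.items():
            if not 1 <= p <= n:
                raise ValueError(f"profile {prof.library_label}: position {p} outside target")
            if c > 0 and target.bases[p - 1] == tb:
                raise ValueError(
                    f"profile {prof.library_label}: mass at position {p}, a "
                    f"{tb} tail-base position that tailing cannot observe"
                )

    f = {"X": profile_x.f1000, "Y": profile_y.f1000}
    fx = lambda p: f["X"].get(p, 0.0)
    fy = lambda p: f["Y"].get(p, 0.0)
    tail_of = {"X": tail_x, "Y": tail_y}
    other = {"X": "Y", "Y": "X"}
    est: Dict[str, Dict[int, float]] = {"X": {}, "Y": {}}
    # case label recorded when a position's estimate is fixed before its merge
    pending_label: Dict[int, str] = {}
    results: Dict[int, PositionResult] = {}
    warnings: List[str] = []

    def observed(lib: str, p: int) -> float:
        return f[lib].get(p, 0.0)

    def resolved(lib: str, p: int) -> float:
        return est[lib].get(p, observed(lib, p))

    def warn(msg: str) -> None:
        warnings.append(msg)
        print(f"WARNING: {msg}", file=log if log is not None else sys.stderr)

    def emit(p: int, merged: float, label: str, ex=None, ey=None, flags=()) -> None:
        sd = position_sd(ex, ey) if (ex is not None and ey is not None) else 0.0
        results[p] = PositionResult(
            position=p,
            base=target.bases[p - 1],
            merged_f1000=merged,
            case_label=label,
            estimate_x=ex,
            estimate_y=ey,
            sd=sd,
            flags=tuple(flags),
        )

    p = n
    while p >= 1:
        base = target.bases[p - 1]
        if base != tail_x and base != tail_y:
            # case #1: directly observed in both libraries
            ex, ey = resolved("X", p), resolved("Y", p)
            emit(p, _mean(ex, ey), "#1", ex, ey)
            p -= 1
            continue

        # p is the 3'-most unprocessed position of a run of one tail base
        collapsed = "X" if base == tail_x else "Y"  # library blind in this run
        resolving = other[collapsed]
        start = p
        while start > 1 and target.bases[start - 2] == base:
            start -= 1
        run = list(range(start, p + 1))
        anchor = start - 1

        run_vals = {q: resolved(resolving, q) for q in run}
        total_run = sum(run_vals.values())

        if anchor == 0:
            # run at the 5' terminus: the collapsed library lost these reads
            # before mapping; report the resolving library single-source.
            for q in run:
                val = run_vals[q]
                if resolving == "Y":
                    emit(q, val, "unresolvable", ey=val, flags=("unresolvable", "single_source"))
                else:
                    emit(q, val, "unresolvable", ex=val, flags=("unresolvable", "single_source"))
            p = 0
            continue

        anchor_base = target.bases[anchor - 1]
        total_collapsed = resolved(collapsed, anchor)

        if anchor_base == tail_of[resolving]:
            # run ends 5' in the *other* library's ambiguity: case #2 (or #3)
            correction = total_collapsed - total_run
            # tolerance guards against float rounding masquerading as a
            # genuine incongruency on congruent libraries
            if correction < -1e-9 * max(total_collapsed, total_run, 1.0):
                # case #3: incongruent libraries
                est[collapsed][anchor] = 0.0
                pending_label[anchor] = "#3"
                window_mean = _mean(total_collapsed, total_run)
                warn(
                    f"{target.id}: incongruency at positions {anchor}-{p}: "
                    f"{profile_x.library_label if collapsed == 'X' else profile_y.library_label} "
                    f"window mass {total_collapsed:.2f} < resolved run mass "
                    f"{total_run:.2f}; anchor clamped to 0 (case #3)"
                )
                for q in run:
                    share = run_vals[q] / total_run if total_run > 0 else 1.0 / len(run)
                    val = window_mean * share
                    emit(q, val, "#3", val, val, flags=("incongruent",))
            else:
                est[collapsed][anchor] = max(correction, 0.0)
                pending_label[anchor] = "#2"
                for q in run:
                    val = run_vals[q]
                    label = pending_label.get(q, "single-source")
                    if label == "#3":
                        kw_flags = ("incongruent",)
                    elif label == "single-source":
                        kw_flags = ("single_source",)
                    else:
                        kw_flags = ()
                    if resolving == "Y":
                        emit(q, val, label, ey=val, flags=kw_flags)
                    else:
                        emit(q, val, label, ex=val, flags=kw_flags)
            p = anchor  # anchor itself is processed by the next window / case
            continue

        # anchor is a non-tail base in both libraries: case #4
        anchor_resolving = resolved(resolving, anchor)
        total_window = total_run + anchor_resolving
        window_positions = [anchor] + run
        if total_window == 0.0:
            if total_collapsed == 0.0:
                for q in window_positions:
                    emit(q, 0.0, "#1", 0.0, 0.0)
            else:
                # collapsed library carries mass the resolving one cannot
                # distribute: incongruency; assign the mean of the competing
                # totals to the anchor.
                warn(
                    f"{target.id}: incongruency at positions {anchor}-{p}: "
                    f"collapsed mass {total_collapsed:.2f} with no resolving "
                    f"signal in the window; mean assigned to anchor (case #3)"
                )
                val = _mean(total_collapsed, 0.0)
                emit(anchor, val, "#3", val, val, flags=("incongruent",))
                for q in run:
                    emit(q, 0.0, "#3", 0.0, 0.0, flags=("incongruent",))
        else:
            sf = total_collapsed / total_window
            run_is_empty = total_run == 0.0
            for q in window_positions:
                res_val = run_vals[q] if q in run_vals else anchor_resolving
                col_val = res_val * sf
                est[collapsed][q] = col_val
                ex = col_val if collapsed == "X" else res_val
                ey = col_val if collapsed == "Y" else res_val
                label = pending_label.get(q)
                if label is None:
                    # zero resolved run mass degenerates to a plain average
                    label = "#1" if (q == anchor and run_is_empty) else "#4"
                emit(q, _mean(ex, ey), label, ex, ey)
        p = anchor - 1

    merged_total = _mean(profile_x.total_mapped, profile_y.total_mapped)

    # guard against float drift / exotic incongruencies: renormalize the
    # resolvable mass to 1000 if needed (logged, not silent)
    resolvable = [r for r in results.values() if "unresolvable" not in r.flags]
    s = sum(r.merged_f1000 for r in resolvable)
    if s > 0 and abs(s - 1000.0) > 1e-6:
        scale = 1000.0 / s
        warn(
            f"{target.id}: merged f1000 mass {s:.6f} != 1000; renormalizing "
            f"(factor {scale:.6f})"
        )
        for r in resolvable:
            r.merged_f1000 *= scale
            r.sd *= scale

    return MergeResult(
        target_id=target.id,
        label_x=profile_x.library_label,
        label_y=profile_y.library_label,
        tail_x=tail_x,
        tail_y=tail_y,
        positions=dict(sorted(results.items())),
        warnings=warnings,
        merged_total=merged_total,
    )


def collapse_distribution(
    true_dist: Dict[int, float], ambiguity: AmbiguityMap
) -> Dict[int, float]:
    """What a tailed library reports for a known true 3'-end distribution:
    each window's run mass is added to its anchor; direct positions pass
    through.  Mass on unresolvable positions (run at the 5' terminus) is an
    error - those reads are lost before mapping."""
    collapsed: Dict[int, float] = {}
    for pos, mass in true_dist.items():
        cls = ambiguity.classification.get(pos)
        if cls is None:
            raise ValueError(f"position {pos} outside target {ambiguity.target_id}")
        if cls == UNRESOLVABLE:
            raise ValueError(
                f"true distribution has mass at unresolvable position {pos} "
                f"(tail-base run at the target 5' terminus)"
            )
        if cls == TRIMMED:
            window = ambiguity.window_at(pos)
            dest = window.anchor
        else:
            dest = pos
        collapsed[dest] = collapsed.get(dest, 0.0) + mass
    return collapsed
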
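"""Deterministic simulation of the profile a tailed library would report.

Given a reference profile assumed to be the truth (typically from a
3'-adapter-ligated library, which has no homopolymer blind spots), predict
what a polyA- or polyC-tailed library of a chosen sequencing depth would
see: counts are rescaled by SF = total_target / total_reference, and the
mass of every ambiguity window (anchor + tail-base run) collapses onto the
anchor.  This is an expectation, not a Monte-Carlo resampling - counts are
kept as real numbers and rounded only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .merge import AmbiguityMap, annotate_ambiguity, DIRECT, ANCHOR, TRIMMED, UNRESOLVABLE
from .profile import EndProfile, TargetSeq

__all__ = ["SimulatedProfile", "simulate_tailed_profile", "compare_profiles"]


@dataclass
class SimulatedProfile:
    """Expected per-position counts of a simulated tailed library."""

    target_id: str
    tail_base: str
    sf: float
    counts: Dict[int, float]
    total: float
    ambiguity: AmbiguityMap

    @property
    def fractions(self) -> Dict[int, float]:
        return {p: c / self.total for p, c in self.counts.items()}

    def window_mass(self, anchor: int) -> float:
        """Collapsed count sitting at a window anchor."""
        return self.counts.get(anchor, 0.0)


def simulate_tailed_profile(
    reference: EndProfile,
    target: TargetSeq,
    tail_base: str,
    total_target: float,
) -> SimulatedProfile:
    """Predict the profile a ``tail_base``-tailed library of depth
    ``total_target`` would report if ``reference`` were the truth."""
    if reference.total_mapped <= 0:
        raise ValueError("reference profile has no mapped reads")
    if total_target <= 0:
        raise ValueError("total_target must be positive")
    if reference.target_id != target.id:
        raise ValueError("reference profile and target do not match")
    amap = annotate_ambiguity(target, tail_base)
    sf = total_target / reference.total_mapped
    counts: Dict[int, float] = {}
    for pos, c in sorted(reference.counts.items()):
        cls = amap.classification.get(pos)
        if cls is None:
            raise ValueError(f"reference position {pos} outside target {target.id}")
        if cls == UNRESOLVABLE:
            raise ValueError(
                f"reference mass at unresolvable position {pos} "
                f"(tail-base run at the target 5' terminus)"
            )
        dest = amap.window_at(pos).anchor if cls == TRIMMED else pos
        counts[dest] = counts.get(dest, 0.0) + c * sf
    return SimulatedProfile(
        target_id=target.id,
        tail_base=tail_base,
        sf=sf,
        counts=counts,
        total=float(total_target),
        ambiguity=amap,
    )


def compare_profiles(
    simulated: SimulatedProfile, experimental: EndProfile
) -> List[Tuple[int, float, float, float]]:
    """Per-position (position, simulated fraction, experimental fraction,
    difference) for a simulated vs an experimental library of the same
    chemistry on the same target."""
    if simulated.target_id != experimental.target_id:
        raise ValueError("profiles are on different targets")
    if experimental.tail_base is not None and experimental.tail_base != simulated.tail_base:
        raise ValueError("profiles use different tail bases")
    sim_frac = simulated.fractions
    exp_frac = {p: c / experimental.total_mapped for p, c in experimental.counts.items()}
    rows = []
    for p in sorted(set(sim_frac) | set(exp_frac)):
        s = sim_frac.get(p, 0.0)
        e = exp_frac.get(p, 0.0)
        rows.append((p, s, e, s - e))
    return rows
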
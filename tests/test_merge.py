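"""Two-library merge: ambiguity annotation, the four cases, and invariants.

The full-precision expected values for the published pRNA worked example are
computed here with exact rational arithmetic by transliterating the 3'->5'
hand procedure step by step (a spreadsheet-style oracle independent of the
general window-resolution implementation).
"""

import io
import math
from fractions import Fraction as F

import pytest
from hypothesis import given, settings, strategies as st

import tailend as te
from tailend.merge import Window, UNRESOLVABLE

from conftest import PRNA_SEQ, POLYA_COUNTS, POLYC1_COUNTS


class TestAnnotateAmbiguity:
    def test_tail_a_windows(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "A")
        assert amap.windows == [Window(8, 9, 12), Window(14, 15, 15)]

    def test_tail_c_windows(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "C")
        assert amap.windows == [Window(3, 4, 4), Window(7, 8, 8), Window(12, 13, 13)]

    def test_run_at_5prime_terminus_is_unresolvable(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "G")
        assert amap.windows[0] == Window(0, 1, 1)
        assert amap.classification[1] == UNRESOLVABLE

    def test_non_run_positions_are_direct(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "A")
        assert amap.classification[5] == "direct"
        assert amap.classification[8] == "anchor"
        assert amap.classification[10] == "trimmed"


def _worked_example_oracle():
    """Exact hand execution of the published merge on the Table-2 counts."""
    fX = {p: F(1000 * c, 581) for p, c in POLYA_COUNTS.items()}
    fY = {p: F(1000 * c, 1530) for p, c in POLYC1_COUNTS.items()}
    gx = lambda p: fX.get(p, F(0))
    gy = lambda p: fY.get(p, F(0))
    merged = {}
    # window A15 with anchor U14 (ab initio case #4)
    sf = gx(14) / (gy(14) + gy(15))
    merged[15] = (gy(15) + gy(15) * sf) / 2
    merged[14] = (gy(14) + gy(14) * sf) / 2
    # window C13 with anchor A12: subtraction goes negative -> case #3
    assert gy(12) - gx(13) < 0
    estY12 = F(0)
    merged[13] = (gy(12) + gx(13)) / 2
    # window A9-A12 with anchor C8: case #2 (single-source polyC run)
    merged[9], merged[10], merged[11], merged[12] = gy(9), gy(10), gy(11), estY12
    estX8 = gx(8) - (gy(9) + gy(10) + gy(11) + estY12)
    # window C8 with anchor U7: case #4 consuming the case-#2 estimate
    sf2 = gy(7) / (estX8 + gx(7))
    merged[8] = (estX8 + estX8 * sf2) / 2
    merged[7] = (gx(7) + gx(7) * sf2) / 2
    # unambiguous 5' positions
    merged[6] = (gx(6) + gy(6)) / 2
    merged[5] = (gx(5) + gy(5)) / 2
    return merged, estX8


class TestWorkedExample:
    def test_full_precision_agreement_with_hand_oracle(self, prna_merge):
        expected, _ = _worked_example_oracle()
        for p, value in expected.items():
            assert prna_merge.positions[p].merged_f1000 == pytest.approx(
                float(value), abs=1e-9
            ), f"position {p}"

    def test_intermediate_anchor_correction(self, prna_merge):
        # total_A 840 - total_C 731 = 109 at C8 in the polyA library
        _, estX8 = _worked_example_oracle()
        assert prna_merge.positions[8].estimate_x == pytest.approx(float(estX8), abs=1e-9)
        assert round(prna_merge.positions[8].estimate_x) == 109

    def test_published_integer_values(self, prna_merge):
        f = prna_merge.merged_f1000
        assert round(f[13]) == 73
        assert f[12] == 0
        assert round(f[14]) == 65
        assert round(f[15]) == 1
        assert f[9] == pytest.approx(324.84, abs=0.01)

    def test_exactly_one_incongruency_warning(self, prna_merge):
        assert len(prna_merge.warnings) == 1
        assert sum(
            1 for r in prna_merge.positions.values() if "incongruent" in r.flags
        ) == 2  # A12 and C13

    def test_case_labels(self, prna_merge):
        labels = prna_merge.case_labels
        assert labels[5] == labels[6] == "#1"
        assert labels[9] == labels[10] == labels[11] == "single-source"
        assert labels[12] == labels[13] == "#3"
        assert labels[7] == labels[14] == labels[15] == "#4"
        assert labels[8] == "#2"

    def test_merged_read_counts(self, prna_merge):
        counts = te.merged_read_counts(prna_merge)
        assert prna_merge.merged_total == 1055.5
        assert counts[9] == pytest.approx(324.8366 / 1000 * 1055.5, abs=1e-3)
        assert round(counts[9]) == 343
        assert counts[12] == 0

    def test_mass_is_conserved(self, prna_merge):
        assert sum(prna_merge.merged_f1000.values()) == pytest.approx(1000, abs=0.5)

    def test_determinism(self, polya_profile, polyc1_profile, prna_target):
        a = te.merge_two_libraries(polya_profile, polyc1_profile, prna_target, log=io.StringIO())
        b = te.merge_two_libraries(polya_profile, polyc1_profile, prna_target, log=io.StringIO())
        assert a.merged_f1000 == b.merged_f1000
        assert a.warnings == b.warnings


def _scheme_1b_oracle():
    """Mutated target (C8 -> U8): the A9-A12 run becomes an ab initio case #4."""
    fX = {p: F(1000 * c, 581) for p, c in POLYA_COUNTS.items()}
    cY = dict(POLYC1_COUNTS)
    cY.pop(7)
    cY.update({7: 10, 8: 190})
    fY = {p: F(1000 * c, 1530) for p, c in cY.items()}
    gx = lambda p: fX.get(p, F(0))
    gy = lambda p: fY.get(p, F(0))
    merged = {}
    sf = gx(14) / (gy(14) + gy(15))
    merged[15] = (gy(15) + gy(15) * sf) / 2
    merged[14] = (gy(14) + gy(14) * sf) / 2
    merged[13] = (gy(12) + gx(13)) / 2  # case #3 as before
    estY12 = F(0)
    # A9-A12 with non-tail anchor U8: one scaled average over the window
    sf2 = gx(8) / (gy(8) + gy(9) + gy(10) + gy(11) + estY12)
    for p, val in ((8, gy(8)), (9, gy(9)), (10, gy(10)), (11, gy(11)), (12, estY12)):
        merged[p] = (val + val * sf2) / 2
    merged[7] = (gx(7) + gy(7)) / 2  # plain case #1 now
    merged[6] = (gx(6) + gy(6)) / 2
    merged[5] = (gx(5) + gy(5)) / 2
    return merged


@pytest.fixture(scope="module")
def mutated_merge():
    target = te.TargetSeq(id="pRNA_mut", bases="GTTCGGTTAAAACTAGGTG")
    pA = te.EndProfile("pRNA_mut", "polyA", dict(POLYA_COUNTS), 581, tail_base="A")
    cY = dict(POLYC1_COUNTS)
    cY.update({7: 10, 8: 190})
    pC = te.EndProfile("pRNA_mut", "polyC1", cY, 1530, tail_base="C")
    return te.merge_two_libraries(pA, pC, target, log=io.StringIO())


class TestScheme1B:
    def test_values_match_hand_oracle(self, mutated_merge):
        expected = _scheme_1b_oracle()
        for p, value in expected.items():
            assert mutated_merge.positions[p].merged_f1000 == pytest.approx(
                float(value), abs=1e-9
            ), f"position {p}"

    def test_run_is_case_4_on_mutated_sequence(self, mutated_merge):
        labels = mutated_merge.case_labels
        assert labels[8] == labels[9] == labels[10] == labels[11] == "#4"
        assert labels[7] == "#1"

    def test_mass_conserved(self, mutated_merge):
        assert sum(mutated_merge.merged_f1000.values()) == pytest.approx(1000, abs=0.5)


class TestValidation:
    def test_identical_tail_bases_rejected(self, polya_profile, prna_target):
        with pytest.raises(ValueError, match="identical tail bases"):
            te.merge_two_libraries(polya_profile, polya_profile, prna_target)

    def test_target_mismatch_rejected(self, polya_profile, polyc1_profile):
        other = te.TargetSeq(id="other", bases="GTTCGGTCAAAACTAGGTG")
        with pytest.raises(ValueError, match="target"):
            te.merge_two_libraries(polya_profile, polyc1_profile, other)

    def test_mass_at_own_tail_base_rejected(self, prna_target):
        bad = te.EndProfile("6S1_pRNA", "bad", {9: 10}, 10, tail_base="A")
        good = te.EndProfile("6S1_pRNA", "c", {9: 10}, 10, tail_base="C")
        with pytest.raises(ValueError, match="tail-base position"):
            te.merge_two_libraries(bad, good, prna_target)


class TestPositionSd:
    def test_two_estimates(self):
        assert te.position_sd(71, 59) == pytest.approx(12 / math.sqrt(2), abs=1e-12)
        assert round(te.position_sd(71, 59), 2) == 8.49

    def test_equal_estimates(self):
        assert te.position_sd(5.5, 5.5) == 0.0

    def test_single_source_position_is_flagged_with_zero_sd(self, prna_merge):
        r = prna_merge.positions[9]
        assert r.sd == 0.0
        assert "single_source" in r.flags


class TestCollapseDistribution:
    def test_run_mass_moves_to_anchor(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "A")
        truth = {8: 0.1, 9: 0.4, 10: 0.3, 13: 0.2}
        assert te.collapse_distribution(truth, amap) == pytest.approx({8: 0.8, 13: 0.2})

    def test_identity_without_tail_base_mass(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "A")
        truth = {5: 0.5, 13: 0.5}
        assert te.collapse_distribution(truth, amap) == truth

    def test_tail_c_single_position(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "C")
        assert te.collapse_distribution({13: 1.0}, amap) == {12: 1.0}

    def test_unresolvable_mass_is_an_error(self, prna_target):
        amap = te.annotate_ambiguity(prna_target, "G")
        with pytest.raises(ValueError, match="unresolvable"):
            te.collapse_distribution({1: 1.0}, amap)


def _profiles_from_truth(dist, target, totals=(581, 1530)):
    """Collapse a true distribution through A- and C-tailing at given depths."""
    amap_a = te.annotate_ambiguity(target, "A")
    amap_c = te.annotate_ambiguity(target, "C")
    col_a = te.collapse_distribution(dist, amap_a)
    col_c = te.collapse_distribution(dist, amap_c)
    pa = te.EndProfile(target.id, "A-lib", {p: m * totals[0] for p, m in col_a.items()},
                       totals[0], tail_base="A")
    pc = te.EndProfile(target.id, "C-lib", {p: m * totals[1] for p, m in col_c.items()},
                       totals[1], tail_base="C")
    return pa, pc


@st.composite
def _true_distributions(draw):
    n = len(PRNA_SEQ)
    support = draw(
        st.lists(st.integers(min_value=1, max_value=n), min_size=1, max_size=n, unique=True)
    )
    weights = draw(
        st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=len(support),
                 max_size=len(support))
    )
    total = sum(weights)
    return {p: w / total for p, w in zip(support, weights)}


class TestMergeProperties:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dist=_true_distributions(),
           totals=st.tuples(st.integers(100, 10**6), st.integers(100, 10**6)))
    def test_congruent_round_trip_recovers_truth(self, dist, totals, prna_target):
        """Merging the A- and C-collapsed views of any true distribution
        recovers it exactly, with no incongruency warning."""
        pa, pc = _profiles_from_truth(dist, prna_target, totals)
        result = te.merge_two_libraries(pa, pc, prna_target, log=io.StringIO())
        assert result.warnings == []
        merged = result.merged_f1000
        for p in range(1, len(PRNA_SEQ) + 1):
            assert merged.get(p, 0.0) == pytest.approx(
                1000 * dist.get(p, 0.0), abs=1e-6
            ), f"position {p}"

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dist=_true_distributions())
    def test_merged_mass_is_1000(self, dist, prna_target):
        pa, pc = _profiles_from_truth(dist, prna_target)
        result = te.merge_two_libraries(pa, pc, prna_target, log=io.StringIO())
        assert sum(result.merged_f1000.values()) == pytest.approx(1000, abs=0.5)

    def test_identical_profiles_merge_to_themselves(self):
        # a target whose 3' region contains neither tail base
        target = te.TargetSeq(id="t", bases="GTTGGTTGG")
        counts = {5: 10, 7: 30, 9: 60}
        pa = te.EndProfile("t", "a", dict(counts), 100, tail_base="A")
        pc = te.EndProfile("t", "c", dict(counts), 100, tail_base="C")
        result = te.merge_two_libraries(pa, pc, target, log=io.StringIO())
        for p, c in counts.items():
            assert result.merged_f1000[p] == pytest.approx(10.0 * c, abs=1e-9)
        assert result.warnings == []

    def test_case3_count_equals_warning_count(self, prna_merge):
        n_case3_windows = len(
            {p for p, r in prna_merge.positions.items() if r.case_label == "#3"}
        )
        # one window (A12/C13) -> one warning covering its two positions
        assert len(prna_merge.warnings) == 1
        assert n_case3_windows == 2
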
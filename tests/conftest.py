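import pytest

import tailend as te

PRNA_SEQ = "GTTCGGTCAAAACTAGGTG"

# Published per-length read counts of the 6S-1 pRNA in the three tailed
# libraries; collapsed classes sit at their window anchors (8-12-mers at 8,
# 14/15-mers at 14 for polyA; 7/8-mers at 7, 12/13-mers at 12 for polyC).
POLYA_COUNTS = {5: 4, 6: 2, 7: 4, 8: 488, 13: 48, 14: 35}          # total 581
POLYC1_COUNTS = {6: 3, 7: 200, 9: 497, 10: 368, 11: 253, 12: 98, 14: 109, 15: 2}  # total 1530


@pytest.fixture(scope="session")
def prna_target():
    return te.TargetSeq(id="6S1_pRNA", bases=PRNA_SEQ)


@pytest.fixture(scope="session")
def polya_profile(prna_target):
    return te.EndProfile(
        target_id=prna_target.id,
        library_label="polyA",
        counts=dict(POLYA_COUNTS),
        total_mapped=581,
        tail_base="A",
    )


@pytest.fixture(scope="session")
def polyc1_profile(prna_target):
    return te.EndProfile(
        target_id=prna_target.id,
        library_label="polyC1",
        counts=dict(POLYC1_COUNTS),
        total_mapped=1530,
        tail_base="C",
    )


@pytest.fixture(scope="session")
def prna_merge(polya_profile, polyc1_profile, prna_target):
    import io
    return te.merge_two_libraries(
        polya_profile, polyc1_profile, prna_target, log=io.StringIO()
    )


@pytest.fixture(scope="session")
def trna_target():
    rec = te.read_fasta(te.example_data_path("trna_glu_3p_synthetic.fasta"))[0]
    return te.TargetSeq(id=rec.id, bases=rec.bases)


@pytest.fixture(scope="session")
def trna_adapter_reference(trna_target):
    table = te.read_count_table(
        te.example_data_path("trna_glu_adapter_counts_synthetic.tsv")
    )
    return te.profile_from_count_table(table, label="adapter")
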
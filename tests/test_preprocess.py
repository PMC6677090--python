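import random

import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from mirseq.preprocess import (
    CleaningReport,
    FastqFormatError,
    TagSet,
    clean_reads,
    collapse_tags,
    compare_libraries,
    length_distribution,
)
from .conftest import ADAPTER3

VALID_22MER = "ACGTACGTACGTACGTACGTAC"


def test_crafted_five_read_fixture_partitions_into_categories(fastq_writer):
    """One read per removal rule plus one survivor, by construction."""
    records = [
        ("polyA", "A" * 22 + ADAPTER3, None),              # homopolymer insert
        ("short", "ACGTACGTACGTACG" + ADAPTER3, None),     # 15 nt after trim
        ("noadapter", "ACGTTGCAACGTTGCAACGTTGCAACGTTG", None),  # adapter absent
        ("hasN", "ACGTNCGTACGTACGTACGTAC" + ADAPTER3, None),
        ("good", VALID_22MER + ADAPTER3, None),
    ]
    survivors, report = clean_reads(fastq_writer(records), adapter3=ADAPTER3)
    assert survivors == [VALID_22MER]
    assert report.clean_reads == 1
    assert report.removed_polyACGT == 1
    assert report.removed_length == 1
    assert report.removed_no3adapter == 1
    assert report.removed_polyN == 1
    assert report.removed_low_quality == 0
    assert report.removed_5adapter == 0
    report.check_conservation()


def test_empty_fastq_gives_all_zero_report(fastq_writer):
    survivors, report = clean_reads(fastq_writer([]), adapter3=ADAPTER3)
    assert survivors == []
    assert report.raw_reads == 0 and report.clean_reads == 0
    assert report.removed_total() == 0


def test_all_valid_reads_all_survive(fastq_writer):
    records = [(f"r{i}", VALID_22MER + ADAPTER3, None) for i in range(100)]
    survivors, report = clean_reads(fastq_writer(records), adapter3=ADAPTER3)
    assert report.clean_reads == 100 and report.removed_total() == 0
    assert survivors == [VALID_22MER] * 100


def test_low_quality_rule_claims_before_all_others(fastq_writer):
    # would also fail poly-N and adapter rules, but low quality has precedence
    records = [("lowq", "N" * 22, "!" * 22)]
    _, report = clean_reads(fastq_writer(records), adapter3=ADAPTER3)
    assert report.removed_low_quality == 1 and report.removed_polyN == 0


def test_five_prime_adapter_contamination(fastq_writer):
    adapter5 = "GTTCAGAGTTCTACAGTCCGACGATC"
    records = [("contaminated", adapter5 + VALID_22MER, None)]
    _, report = clean_reads(
        fastq_writer(records), adapter3=ADAPTER3, adapter5=adapter5
    )
    assert report.removed_5adapter == 1


def test_no_adapter_arguments_skips_adapter_rules(fastq_writer):
    records = [("r", VALID_22MER, None)]
    survivors, report = clean_reads(fastq_writer(records))
    assert survivors == [VALID_22MER]
    assert report.removed_no3adapter == 0


def test_malformed_fastq_is_a_hard_error(tmp_path):
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\n+\nII\n")  # quality shorter than sequence
    with pytest.raises(FastqFormatError):
        clean_reads(bad, adapter3=ADAPTER3)


@settings(
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
@given(
    kinds=st.lists(st.integers(min_value=0, max_value=6), max_size=60),
    seed=st.integers(0, 2**31 - 1),
)
def test_cleaning_report_conserves_reads_on_random_mixtures(kinds, seed, tmp_path):
    """category counts + clean reads == raw reads, whatever the input mix."""
    rng = random.Random(seed)
    records = []
    for i, kind in enumerate(kinds):
        if kind == 0:
            seq = VALID_22MER + ADAPTER3
            qual = None
        elif kind == 1:
            seq = "A" * rng.randint(18, 30) + ADAPTER3
            qual = None
        elif kind == 2:
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(8, 40)))
            qual = None
        elif kind == 3:
            seq = VALID_22MER + ADAPTER3
            qual = "!" * len(seq)
        elif kind == 4:
            seq = "ACGTN" + VALID_22MER + ADAPTER3
            qual = None
        elif kind == 5:
            seq = "".join(rng.choice("ACGT") for _ in range(5)) + ADAPTER3
            qual = None
        else:
            seq = VALID_22MER[: rng.randint(1, 22)] + ADAPTER3 + VALID_22MER
            qual = None
        records.append((f"r{i}", seq, qual))
    path = tmp_path / "mix.fastq"
    with open(path, "w") as fh:
        for name, seq, qual in records:
            qual = qual or "I" * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    _, report = clean_reads(path, adapter3=ADAPTER3)
    assert report.raw_reads == len(records)
    report.check_conservation()


@pytest.mark.parametrize(
    "reads,expected",
    [
        (["S1", "S1", "S1", "S2"], {"S1": 3, "S2": 1}),
        ([], {}),
        ([f"S{i}" for i in range(10)], {f"S{i}": 1 for i in range(10)}),
    ],
)
def test_collapse_tags_merges_and_preserves_totals(reads, expected):
    tags = collapse_tags(reads, "lib")
    assert tags.counts == expected
    assert tags.total_reads == len(reads)


def test_length_distribution_fractions_are_over_reads():
    tags = TagSet(counts={"A" * 22: 47, "C" * 21: 53}, library_label="x")
    dist = length_distribution(tags).set_index("length")
    assert dist.loc[22, "fraction"] == pytest.approx(0.47)
    assert dist["fraction"].sum() == pytest.approx(1.0)


def test_length_distribution_single_tag_and_empty_error():
    dist = length_distribution(TagSet(counts={"A" * 20: 5}))
    assert dist["fraction"].tolist() == [1.0]
    with pytest.raises(ValueError):
        length_distribution(TagSet(counts={}))


def test_compare_libraries_hand_enumerated_example():
    a = TagSet(counts={"T1": 5, "T2": 1}, library_label="a")
    b = TagSet(counts={"T2": 2, "T3": 4}, library_label="b")
    comp = compare_libraries(a, b)
    assert comp.common_unique == 1
    assert comp.a_specific_unique == 1 and comp.b_specific_unique == 1
    assert comp.common_total == 3
    assert comp.common_total_fraction == pytest.approx(3 / 12)
    assert comp.grand_total == 12


def test_compare_libraries_disjoint_and_identical_cases():
    a = TagSet(counts={"T1": 2})
    b = TagSet(counts={"T2": 3})
    comp = compare_libraries(a, b)
    assert comp.common_unique == 0 and comp.common_total == 0
    same = compare_libraries(a, TagSet(counts={"T1": 7}))
    assert same.a_specific_total == 0 and same.b_specific_total == 0
    assert same.common_total_fraction == pytest.approx(1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.dictionaries(st.sampled_from(["T1", "T2", "T3", "T4"]), st.integers(1, 50)),
    st.dictionaries(st.sampled_from(["T2", "T3", "T5"]), st.integers(1, 50)),
)
def test_compare_libraries_is_symmetric(ca, cb):
    a, b = TagSet(counts=ca), TagSet(counts=cb)
    ab, ba = compare_libraries(a, b), compare_libraries(b, a)
    assert ab.common_unique == ba.common_unique
    assert ab.common_total == ba.common_total
    assert ab.a_specific_total == ba.b_specific_total
    assert ab.a_specific_unique == ba.b_specific_unique
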
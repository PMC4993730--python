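"""Cleaning filters, tag collapsing, length distributions and overlap."""

import pytest
from hypothesis import given, settings, strategies as st

from srnaphase import preprocess
from srnaphase.preprocess import (
    RawRead,
    TagLibrary,
    classify_read,
    clean_reads,
    collapse_tags,
    length_distribution,
    library_overlap,
)
from srnaphase.seq import DEFAULT_ADAPTER3 as A3, DEFAULT_ADAPTER5 as A5
from srnaphase.synthetic import SyntheticConfig, generate_reference_bundle, simulate_libraries

GOOD_INSERT = "TGAGGTAGTAGATTGTATAGTT"  # 22 nt


def _read(seq, qual_char="I"):
    return RawRead("r1", seq, [ord(qual_char) - 33] * len(seq))


@pytest.mark.parametrize(
    "seq,expected",
    [
        # 5' adapter at the front of the insert -> contaminant
        ((A5 + "GT" + A3)[:40].ljust(40, "G"), "5adapter_contaminants"),
        # clean 22-nt insert followed by the 3' adapter
        (GOOD_INSERT + A3, "clean"),
        # 15-nt insert -> shorter than 18 nt
        ("TGAGGTAGTAGATTG" + A3, "smaller_than_18nt"),
        # poly-A insert
        ("A" * 25 + A3, "polyA"),
        # adapter at position 0 -> null insert
        (A3 + "ACGTACGTACGTACGTACG", "insert_null"),
        # no adapter anywhere -> 3' adapter null
        ("ACGTTGCAGTCAGGTCAACGGTTACCATGGCAACGTTCAA", "3adapter_null"),
    ],
)
def test_filter_categories_on_constructed_reads(seq, expected):
    category, _ = classify_read(_read(seq))
    assert category == expected


def test_clean_read_is_trimmed_to_insert():
    inserts, stats = clean_reads([_read(GOOD_INSERT + A3)])
    assert inserts == [GOOD_INSERT]
    assert stats.clean_reads == 1


def test_low_quality_read_removed_first():
    # read would also fail the adapter filter, but quality is checked first
    read = RawRead("r1", "ACGT" * 10, [2] * 40)
    category, _ = classify_read(read)
    assert category == "low_quality"


def test_n_bases_flag_low_quality():
    category, _ = classify_read(_read("ACGTN" + GOOD_INSERT + A3))
    assert category == "low_quality"


def test_empty_input_yields_zero_stats():
    inserts, stats = clean_reads([])
    assert inserts == [] and stats.total_reads == 0
    stats.validate()


def test_malformed_record_names_the_read():
    with pytest.raises(ValueError, match="bad_id"):
        classify_read(RawRead("bad_id", "ACGTX" + A3, None))


def test_cleaning_is_idempotent():
    """Re-cleaning survivors (re-ligated to the adapter) removes nothing."""
    raw = [_read(GOOD_INSERT + A3), _read("ACGTGTCAGGTAACCGTAGGTCAAG" + A3)]
    inserts, _ = clean_reads(raw)
    again, stats = clean_reads([_read(i + A3) for i in inserts])
    assert again == inserts
    assert stats.clean_reads == stats.total_reads


def test_read_conservation_partition(small_config):
    """Every raw read lands in exactly one category on synthetic data."""
    cfg = small_config.synthetic
    bundle = generate_reference_bundle(cfg)
    libs, truth = simulate_libraries(cfg, bundle)
    reads = (RawRead(r, s, [ord(c) - 33 for c in q]) for r, s, q in libs["Fols"])
    _, stats = clean_reads(reads, cfg.adapter5, cfg.adapter3)
    stats.validate()
    assert stats.total_reads == len(libs["Fols"])


def test_planted_contaminants_recovered_exactly():
    """Each contaminant class is constructed to fail exactly its filter."""
    cfg = SyntheticConfig(seed=11, n_reads_per_lib=8_000,
                          contaminant_rates={
                              "low_quality": 0.01, "3adapter_null": 0.01,
                              "insert_null": 0.01, "5adapter_contaminant": 0.01,
                              "smaller_than_18nt": 0.01, "polyA": 0.01})
    bundle = generate_reference_bundle(cfg)
    libs, truth = simulate_libraries(cfg, bundle)
    for lib in ("Fols", "Luts"):
        reads = (RawRead(r, s, [ord(c) - 33 for c in q]) for r, s, q in libs[lib])
        _, stats = clean_reads(reads, cfg.adapter5, cfg.adapter3)
        planted = truth.read_label_counts[lib]
        assert stats.low_quality == planted["low_quality"]
        assert stats.adapter3_null == planted["3adapter_null"]
        assert stats.insert_null == planted["insert_null"]
        assert stats.adapter5_contaminants == planted["5adapter_contaminant"]
        assert stats.smaller_than_18nt == planted["smaller_than_18nt"]
        assert stats.polyA == planted["polyA"]


def test_zero_contaminant_rates_remove_nothing():
    cfg = SyntheticConfig(seed=3, n_reads_per_lib=5_000,
                          contaminant_rates={k: 0.0 for k in
                                             ("low_quality", "3adapter_null",
                                              "insert_null", "5adapter_contaminant",
                                              "smaller_than_18nt", "polyA")})
    bundle = generate_reference_bundle(cfg)
    libs, _ = simulate_libraries(cfg, bundle)
    reads = (RawRead(r, s, [ord(c) - 33 for c in q]) for r, s, q in libs["Fols"])
    _, stats = clean_reads(reads, cfg.adapter5, cfg.adapter3)
    assert stats.clean_reads == stats.total_reads == stats.high_quality


def test_collapse_examples():
    lib = collapse_tags(["AAC" * 7] * 3 + ["GGT" * 7] * 2)
    assert lib.counts == {"AAC" * 7: 3, "GGT" * 7: 2}
    assert collapse_tags([]).counts == {}


@settings(deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["ACGTACGTACGTACGTAC", "TTGGCCAATTGGCCAATT",
                                 "GACGACGACGACGACGAC"]), max_size=200))
def test_collapse_conserves_read_count(reads):
    lib = collapse_tags(reads)
    assert lib.total_reads == len(reads)
    assert all(v > 0 for v in lib.counts.values())


def test_length_distribution_examples():
    lib = TagLibrary("x", {"A" * 22: 5, "C" * 22: 1})
    dist = length_distribution(lib)
    assert dist.fractions == {22: 1.0}
    lib = TagLibrary("x", {"A" * 21: 1, "C" * 22: 3})
    assert length_distribution(lib, "by-read").fractions[22] == 0.75
    assert length_distribution(lib, "by-unique-tag").fractions[22] == 0.5
    with pytest.raises(ValueError):
        length_distribution(TagLibrary("x", {}))


def test_library_overlap_examples():
    a = TagLibrary("A", {"T" * 18: 1, "G" * 18: 1, "C" * 18: 1})
    b = TagLibrary("B", {"G" * 18: 1, "C" * 18: 1, "A" * 18: 1})
    v = library_overlap(a, b)
    assert (v.common_unique, v.specific_a_unique, v.specific_b_unique) == (2, 1, 1)
    assert (v.common_total_reads + v.specific_a_total_reads
            + v.specific_b_total_reads) == a.total_reads + b.total_reads
    disjoint = library_overlap(TagLibrary("A", {"T" * 18: 4}),
                               TagLibrary("B", {"G" * 18: 2}))
    assert disjoint.common_total_reads == 0 and disjoint.common_unique == 0


def test_stats_tsv_has_fixed_row_order(default_report):
    text = preprocess.stats_to_tsv(default_report.cleaning_stats["Fols"],
                                   default_report.cleaning_stats["Luts"])
    rows = [l.split("\t")[0] for l in text.strip().splitlines()]
    assert rows == ["Type", "Total_reads", "High_quality", "3adapter_null",
                    "Insert_null", "5adapter_contaminants", "Smaller_than_18nt",
                    "polyA", "Clean_reads"]
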
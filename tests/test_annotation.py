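"""Genome mapping, the priority rule, known-miRNA identification, rRNA QC."""

import numpy as np
import pytest

from srnaphase.annotation import (
    CompositionTable,
    ReferenceSet,
    annotate_by_priority,
    identify_known_mirnas,
    map_tags_to_genome,
    rrna_qc_check,
    venn_known_mirnas,
)
from srnaphase.preprocess import TagLibrary
from srnaphase.seq import revcomp
from srnaphase.synthetic import Feature, KnownMirna, SyntheticConfig, generate_reference_bundle


def _rand_genome(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_map_constructed_tags():
    genome = _rand_genome(2_000)
    tag = genome[100:122]
    rc_tag = revcomp(genome[500:523])
    lib = TagLibrary("x", {tag: 1, rc_tag: 1})
    hits = map_tags_to_genome(lib, genome)
    assert (100, "+") in hits[tag]
    assert (500, "-") in hits[rc_tag]


def test_absent_tag_has_no_hits_vs_scan_oracle():
    genome = _rand_genome(10_000, seed=1)
    rng = np.random.default_rng(2)
    for _ in range(5):
        tag = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        expected = []
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            p = genome.find(query)
            while p >= 0:
                expected.append((p, strand))
                p = genome.find(query, p + 1)
        hits = map_tags_to_genome(TagLibrary("x", {tag: 1}), genome)[tag]
        assert hits == sorted(expected)


def _tiny_refs(features):
    genome = _rand_genome(1_000, seed=3)
    tracks = {c: [] for c in ("rrna_etc", "known_mirna", "pirna", "repeat",
                              "exon", "intron")}
    for cat, start, end in features:
        tracks[cat].append(Feature("chr1", "t", cat, start, end, "+", f"{cat}_{start}"))
    return genome, ReferenceSet(genome=genome, tracks=tracks, mirnas=[])


@pytest.mark.parametrize(
    "features,expected",
    [
        ([("rrna_etc", 100, 140), ("known_mirna", 100, 140)], "rrna_etc"),
        ([("exon", 100, 140), ("intron", 100, 140)], "exon"),
        ([], "unann"),
    ],
)
def test_priority_rule(features, expected):
    genome, refs = _tiny_refs(features)
    tag = genome[105:127]
    lib = TagLibrary("x", {tag: 2})
    hits = map_tags_to_genome(lib, genome)
    records, comp = annotate_by_priority(lib, refs, hits)
    assert records[0].category == expected


def test_priority_invariant_to_track_input_order():
    genome, refs = _tiny_refs([("intron", 100, 140), ("repeat", 100, 140),
                               ("exon", 300, 340)])
    reversed_refs = ReferenceSet(genome=genome,
                                 tracks={c: list(reversed(v))
                                         for c, v in refs.tracks.items()},
                                 mirnas=[])
    lib = TagLibrary("x", {genome[105:127]: 1, genome[305:327]: 1})
    hits = map_tags_to_genome(lib, genome)
    cats1 = [r.category for r in annotate_by_priority(lib, refs, hits)[0]]
    cats2 = [r.category for r in annotate_by_priority(lib, reversed_refs, hits)[0]]
    assert cats1 == cats2 == sorted(cats1)  # deterministic, order-free


def test_composition_fractions_sum_to_one(default_report):
    for lib in ("Fols", "Luts"):
        comp = default_report.compositions[lib]
        for sense in ("unique", "total"):
            assert sum(comp.fractions(sense).values()) == pytest.approx(1.0)


def _single_mirna_refs(mature="TGAGGTAGTAGATTGTATAGTT", mid="chi-let-7f-5p"):
    rng = np.random.default_rng(9)
    ext = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
    loop = "".join("ACGT"[i] for i in rng.integers(0, 4, 11))
    pre = ext + mature + loop + revcomp(mature) + ext
    mirna = KnownMirna(mid, mature, pre, 8, "5p", 0, "+")
    return ReferenceSet(genome=pre, tracks={}, mirnas=[mirna])


def test_identical_tag_assigned_to_known_mirna():
    refs = _single_mirna_refs()
    lib = TagLibrary("x", {"TGAGGTAGTAGATTGTATAGTT": 7})
    counts, detected, assign = identify_known_mirnas(lib, refs, max_mismatch=0)
    assert counts["chi-let-7f-5p"] == 7 and detected == {"chi-let-7f-5p"}


def test_mismatch_tolerance():
    refs = _single_mirna_refs()
    one_sub = "TGAGGTAGTAGATTGTATAGTA"   # 1 substitution at the 3' end
    five_sub = "TGAGGTAGCCCCTTGTATAGTA"
    lib = TagLibrary("x", {one_sub: 3, five_sub: 2})
    counts, detected, assign = identify_known_mirnas(lib, refs, max_mismatch=2)
    assert assign[one_sub] == "chi-let-7f-5p"
    assert five_sub not in assign
    counts0, _, assign0 = identify_known_mirnas(lib, refs, max_mismatch=0)
    assert one_sub not in assign0


def test_in_window_length_variants_are_assigned():
    refs = _single_mirna_refs()
    pre = refs.mirnas[0].precursor
    variant = pre[7:31]  # one nt upstream, two nt longer
    lib = TagLibrary("x", {variant: 4})
    counts, _, assign = identify_known_mirnas(lib, refs, max_mismatch=0)
    assert assign[variant] == "chi-let-7f-5p"


def test_planted_matures_recovered_without_mismatches(default_report):
    """Every planted known tag emitted unmutated is found at max_mismatch=0."""
    truth = default_report.truth
    for p, lib in enumerate(("Fols", "Luts")):
        counts = default_report.known_counts[lib]
        for mid, planted in truth.mirna_counts.items():
            if planted[p] > 0:
                assert counts[mid] > 0, (lib, mid)


def test_venn_known_mirna_arithmetic():
    a = {f"m{i}" for i in range(10)}
    b = {f"m{i}" for i in range(6, 16)}
    v = venn_known_mirnas(a, b)
    assert v == {"co_expressed": 4, "a_specific": 6, "b_specific": 6,
                 "total_a": 10, "total_b": 10}
    assert venn_known_mirnas(set("ab"), set("cd"))["co_expressed"] == 0


@pytest.mark.parametrize("rrna_frac,kingdom,expected",
                         [(0.1704, "animal", True), (0.45, "animal", False),
                          (0.0, "animal", True), (0.45, "plant", True)])
def test_rrna_qc_thresholds(rrna_frac, kingdom, expected):
    total = 1_000_000
    comp = CompositionTable("x", unique={},
                            total={"rrna_etc": int(rrna_frac * total),
                                   "known_mirna": total - int(rrna_frac * total)})
    ok, proportion = rrna_qc_check(comp, kingdom)
    assert ok is expected
    assert proportion == pytest.approx(rrna_frac, abs=1e-6)


def test_reference_roundtrip_through_files(tmp_path):
    cfg = SyntheticConfig(n_known_mirnas=10, n_genes=30, genome_len=60_000)
    bundle = generate_reference_bundle(cfg)
    bundle.write(tmp_path)
    refs = ReferenceSet.from_dir(tmp_path)
    assert refs.genome == bundle.genome
    assert {m.id for m in refs.mirnas} == {m.id for m in bundle.mirnas}
    by_id = {m.id: m for m in refs.mirnas}
    for m in bundle.mirnas:
        assert by_id[m.id].precursor == m.precursor
        assert by_id[m.id].mat_offset == m.mat_offset
    n_feats = sum(len(v) for v in refs.tracks.values())
    assert n_feats == sum(len(v) for v in
                          ReferenceSet.from_bundle(bundle).tracks.values())
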
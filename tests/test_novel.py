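"""Locus clustering, hairpin folding and novel-miRNA calling."""

import numpy as np
import pytest

from srnaphase.novel import (
    CandidateCriteria,
    GenomicLocus,
    call_novel_mirnas,
    cluster_unannotated,
    evaluate_candidate,
    fold_hairpin,
    pair_table,
)
from srnaphase.seq import revcomp


def _seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# --- clustering -----------------------------------------------------------

def test_cluster_merges_nearby_same_strand_hits():
    hits = {"A" * 22: [(100, "+")], "C" * 22: [(132, "+")]}
    loci = cluster_unannotated(hits, {"A" * 22: 3, "C" * 22: 2}, max_gap=50)
    assert len(loci) == 1 and loci[0].start == 100 and loci[0].end == 154


def test_cluster_separates_strands_and_distant_hits():
    hits = {"A" * 22: [(100, "+")], "C" * 22: [(100, "-")]}
    assert len(cluster_unannotated(hits, {}, 50)) == 2
    hits = {"A" * 22: [(100, "+")], "C" * 22: [(322, "+")]}
    assert len(cluster_unannotated(hits, {}, 50)) == 2


def test_dominant_tag_tie_break_is_lexicographic():
    locus = GenomicLocus("chr1", 0, 40, "+",
                         [("TTT" + "A" * 19, 5, 0), ("AAA" + "C" * 19, 5, 10)])
    assert locus.dominant()[0].startswith("AAA")


# --- folding --------------------------------------------------------------

def test_perfect_inverted_repeat_folds_to_single_stem():
    stem = _seq(30, seed=4)
    hairpin = stem + "AACCTTGG" + revcomp(stem)
    structure, score = fold_hairpin(hairpin)
    assert score >= 30
    assert len(structure) == len(hairpin)
    pt = pair_table(structure)  # raises on unbalanced brackets
    # a single hairpin loop: exactly one innermost loop region
    import re
    assert len(re.findall(r"\([.]*\)", structure)) == 1
    # the stem arm pairs across the loop: no pair stays within the first arm
    assert all(pt[i] >= 30 for i in range(30) if i in pt)
    # and nearly all of it reaches the complementary arm proper
    assert sum(1 for i in range(30) if pt.get(i, -1) >= 38) >= 28


def test_polyA_folds_to_zero_pairs():
    structure, score = fold_hairpin("A" * 80)
    assert score == 0 and set(structure) == {"."}


def test_reverse_complement_folds_to_mirrored_equal_score():
    # Watson-Crick-only stem: the pairing rule set is strand-symmetric here
    stem = "".join(np.random.default_rng(7).choice(list("ACGT"), 25))
    seq = stem + "TTTCAAA" + revcomp(stem)
    s1, score1 = fold_hairpin(seq)
    s2, score2 = fold_hairpin(revcomp(seq))
    assert score1 == score2
    mirrored = s1[::-1].translate(str.maketrans("()", ")("))
    assert sorted(pair_table(s2)) == sorted(pair_table(mirrored))


def test_fold_rejects_invalid_characters():
    with pytest.raises(ValueError):
        fold_hairpin("ACGTX" * 20)


def test_fold_scores_match_enumeration_oracle():
    """Base-pair maximisation agrees with exhaustive enumeration (tiny n)."""
    from itertools import combinations

    def oracle(s):
        n = len(s)
        pairs = [(i, j) for i in range(n) for j in range(i + 4, n)
                 if (s[i], s[j]) in {("A", "T"), ("T", "A"), ("G", "C"),
                                     ("C", "G"), ("G", "T"), ("T", "G")}]
        best = 0
        # enumerate all non-crossing matchings up to size 3 on short strings
        for k in range(min(3, len(pairs)), 0, -1):
            for combo in combinations(pairs, k):
                used = set()
                ok = True
                for (i, j) in combo:
                    if i in used or j in used:
                        ok = False
                        break
                    used |= {i, j}
                for (i, j), (a, b) in combinations(combo, 2):
                    crossing = (i < a < j < b) or (a < i < b < j)
                    if crossing:
                        ok = False
                        break
                if ok:
                    best = max(best, k)
            if best == k:
                break
        return best

    rng = np.random.default_rng(11)
    for _ in range(12):
        s = "".join(rng.choice(list("ACGT"), 10))
        _, score = fold_hairpin(s)
        assert score == oracle(s), s


# --- candidate evaluation -------------------------------------------------

def _planted_locus(seed=21):
    """A genome with one perfect planted hairpin locus."""
    rng = np.random.default_rng(seed)
    mature = "".join(rng.choice(list("ACGT"), 22))
    star = list(revcomp(mature))
    for p in (5, 15):  # imperfect duplex, as in real miRNA/miRNA* pairs
        star[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[star[p]]
    loop = "".join(rng.choice(list("ACGT"), 12))
    pre = mature + loop + "".join(star)
    genome = _seq(400, seed) + pre + _seq(400, seed + 1)
    locus = GenomicLocus("chr1", 400, 400 + 22, "+", [(mature, 50, 400)])
    return locus, genome


def test_planted_hairpin_accepted():
    locus, genome = _planted_locus()
    cand = evaluate_candidate(locus, genome)
    assert cand.accepted and cand.verdict == "accepted"
    assert cand.arm == "5p"
    assert cand.mature in cand.precursor
    assert len(cand.structure) == len(cand.precursor)
    assert cand.mature_pairs >= 16


def test_unstructured_locus_rejected_with_label():
    genome = _seq(600, seed=33)
    tag = genome[300:322]
    locus = GenomicLocus("chr1", 300, 322, "+", [(tag, 10, 300)])
    cand = evaluate_candidate(locus, genome)
    assert not cand.accepted
    assert cand.verdict in {"no_duplex", "few_mature_pairs",
                            "unpaired_mature_bases", "loop_size", "low_score"}


def test_overlong_mature_rejected_as_length():
    genome = _seq(600, seed=34)
    tag = genome[300:330]  # 30 nt > mature_len_range upper bound
    locus = GenomicLocus("chr1", 300, 330, "+", [(tag, 10, 300)])
    assert evaluate_candidate(locus, genome).verdict == "mature_length"


def test_evaluation_is_deterministic():
    locus, genome = _planted_locus(seed=55)
    c1 = evaluate_candidate(locus, genome)
    c2 = evaluate_candidate(locus, genome)
    assert (c1.structure, c1.verdict, c1.mature_pairs) == \
           (c2.structure, c2.verdict, c2.mature_pairs)


def test_contig_edge_flanks_truncated_not_fatal():
    locus, genome = _planted_locus(seed=77)
    # place the hairpin near the contig start by clipping the genome
    clipped = genome[395:]
    edge_locus = GenomicLocus("chr1", 5, 27, "+", [(locus.tags[0][0], 50, 5)])
    cand = evaluate_candidate(edge_locus, clipped)
    assert cand.accepted


def test_false_positive_rate_on_shuffled_genome():
    """Random loci on a feature-free genome are accepted < 5% of the time."""
    rng = np.random.default_rng(101)
    genome = "".join(rng.choice(list("ACGT"), 40_000))
    accepted = 0
    n = 60
    for k in range(n):
        pos = int(rng.integers(200, len(genome) - 400))
        tag = genome[pos : pos + 22]
        locus = GenomicLocus("chr1", pos, pos + 22, "+", [(tag, 10, pos)])
        accepted += evaluate_candidate(locus, genome).accepted
    assert accepted / n < 0.05


def test_planted_novel_loci_all_recovered(default_report):
    """Recall of expressed planted novel loci is 1 at default criteria."""
    truth = default_report.truth
    called = {m.mature for m in default_report.novel_mirnas}
    for loc in truth.novel_loci:
        if any(loc.expressed.values()):
            assert loc.mature in called, loc.id


def test_call_novel_merging_and_naming():
    locus_a, genome = _planted_locus(seed=91)
    cand_a = evaluate_candidate(locus_a, genome)
    assert cand_a.accepted
    candidates = {"Fols": [cand_a], "Luts": [cand_a]}
    novel, venn = call_novel_mirnas(candidates)
    assert [m.id for m in novel] == ["novel_mir_1"]
    assert venn["co_expressed"] == 1
    assert venn["total_Fols"] == venn["total_Luts"] == 1
    novel2, venn2 = call_novel_mirnas({"Fols": [cand_a], "Luts": []})
    assert venn2 == {"co_expressed": 0, "Fols_specific": 1, "Luts_specific": 0,
                     "total_Fols": 1, "total_Luts": 0}
    assert call_novel_mirnas({"Fols": [], "Luts": []})[0] == []
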
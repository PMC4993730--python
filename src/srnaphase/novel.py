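"""Novel miRNA prediction from unannotated tags.

Unannotated tags that map to the genome are clustered into strand-specific
loci; each locus is evaluated as a potential miRNA gene by extracting the
dominant tag with asymmetric flanks (both arm placements are tried),
folding the putative precursor, and applying hairpin criteria patterned on
classic single-locus miRNA predictors: the mature must sit in one arm of a
compact stem-loop, largely base-paired to a single contiguous star region
across a short loop.

The default folding engine is Nussinov-style base-pair maximisation
(minimum hairpin loop 3 nt, G-U wobble allowed) — deterministic and
testable by enumeration.  A thermodynamic model can be plugged in through
``CandidateCriteria.energy_model``; the score criterion then switches from
a paired-fraction threshold to a free-energy ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .preprocess import TagLibrary
from .seq import revcomp

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
MIN_LOOP = 3


@dataclass
class GenomicLocus:
    """A strand-specific cluster of unannotated tag hits."""

    seqid: str
    start: int                 # 0-based half-open
    end: int
    strand: str
    tags: list[tuple[str, int, int]]  # (tag, count, genomic hit position)

    def dominant(self) -> tuple[str, int, int]:
        """Highest-count supporting tag (ties: lexicographically smallest)."""
        return max(self.tags, key=lambda t: (t[1], [-ord(c) for c in t[0]]))


def vienna_fold(seq: str) -> tuple[str, float]:
    """Thermodynamic MFE folding through the ViennaRNA bindings."""
    import RNA

    structure, energy = RNA.fold(seq.upper().replace("T", "U"))
    return structure, float(energy)


def default_energy_model() -> Callable[[str], tuple[str, float]] | None:
    """ViennaRNA MFE folding when the bindings are importable, else None."""
    try:
        import RNA  # noqa: F401
    except ImportError:
        return None
    return vienna_fold


@dataclass
class CandidateCriteria:
    """Acceptance criteria for a hairpin candidate, applied in order.

    ``energy_model`` is the pluggable folding hook: "auto" (default) uses
    thermodynamic MFE folding when the ViennaRNA bindings are available and
    falls back to base-pair maximisation otherwise; ``None`` forces the
    self-contained maximiser; any callable returning (dot-bracket, energy)
    may be supplied.
    """

    flank_short: int = 20
    flank_long: int = 150
    mature_len_range: tuple[int, int] = (18, 26)
    min_mature_pairs: int = 16
    max_unpaired: int = 4
    max_bulge: int = 6            # star span may exceed mature span by this
    loop_range: tuple[int, int] = (3, 60)
    min_paired_frac: float = 0.55
    min_duplex_wc: int = 14       # prefilter: best WC-only duplex match
    energy_model: Callable[[str], tuple[str, float]] | None | str = "auto"
    max_energy: float = -18.0     # kcal/mol ceiling when energy_model is set

    def resolve_energy_model(self) -> Callable[[str], tuple[str, float]] | None:
        if self.energy_model == "auto":
            return default_energy_model()
        return self.energy_model


@dataclass
class HairpinCandidate:
    locus: GenomicLocus
    precursor: str
    structure: str
    score: int
    mature: str
    mature_offset: int
    arm: str | None
    mature_pairs: int
    verdict: str                  # "accepted" or the first failed criterion
    accepted: bool


@dataclass
class NovelMiRNA:
    id: str
    mature: str
    precursor: str
    structure: str
    locus: GenomicLocus
    counts: dict[str, int] = field(default_factory=dict)


def cluster_unannotated(
    tag_hits: dict[str, list[tuple[int, str]]],
    counts: dict[str, int],
    max_gap: int = 50,
    seqid: str = "chr1",
) -> list[GenomicLocus]:
    """Merge same-strand tag hits within ``max_gap`` nt into loci.

    Every genome hit of every tag contributes; loci are returned sorted by
    (start, strand).
    """
    events: list[tuple[int, int, str, str, int]] = []
    for tag in sorted(tag_hits):
        for pos, strand in tag_hits[tag]:
            events.append((pos, pos + len(tag), strand, tag, counts.get(tag, 0)))
    loci: list[GenomicLocus] = []
    for strand in ("+", "-"):
        stranded = sorted(e for e in events if e[2] == strand)
        current: GenomicLocus | None = None
        for start, end, _s, tag, count in stranded:
            if current is not None and start - current.end <= max_gap:
                current.end = max(current.end, end)
                current.tags.append((tag, count, start))
            else:
                if current is not None:
                    loci.append(current)
                current = GenomicLocus(seqid, start, end, strand,
                                       [(tag, count, start)])
        if current is not None:
            loci.append(current)
    return sorted(loci, key=lambda l: (l.start, l.strand))


def fold_hairpin(seq: str) -> tuple[str, int]:
    """Fold a precursor by base-pair maximisation; returns (dot-bracket, pairs).

    Pseudoknot-free; hairpin loops of at least ``MIN_LOOP`` nt; A-U, G-C
    and G-U pairs score 1 each.  Deterministic: the traceback prefers
    leaving the 3' base unpaired, then the outermost admissible pairing.
    """
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGT"):
        raise ValueError("fold_hairpin: sequence must be over A/C/G/U(T)")
    n = len(s)
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    # pairable matrix
    comp = np.zeros((256, 256), dtype=bool)
    for a, b in _PAIRS:
        comp[ord(a), ord(b)] = True
    P = comp[codes[:, None], codes[None, :]]

    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # M[i][j] over s[i..j]
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]
            ks = np.nonzero(P[i : j - MIN_LOOP, j])[0]
            if ks.size:
                k = ks + i
                left = np.where(k > i, M[i, np.maximum(k - 1, 0)], 0)
                cand = left + M[k + 1, j - 1] + 1
                best = max(best, int(cand.max()))
            M[i, j] = best

    # traceback
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i, j] == 0:
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            if not P[k, j]:
                continue
            left = M[i, k - 1] if k > i else 0
            if left + M[k + 1, j - 1] + 1 == M[i, j]:
                structure[k], structure[j] = "(", ")"
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return "".join(structure), int(M[0, n - 1])


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    out: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            out[i], out[j] = j, i
    if stack:
        raise ValueError("unbalanced structure string")
    return out


def _best_wc_duplex(mature: str, window: str) -> int:
    """Best ungapped Watson-Crick complementarity of mature vs. the window.

    Cheap star-arm scan used to skip folding of hopeless loci: slides the
    reverse complement of the mature along the window and returns the
    maximum number of matching positions.
    """
    target = revcomp(mature)
    L = len(target)
    if len(window) < L:
        return 0
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    view = np.lib.stride_tricks.sliding_window_view(w, L)
    return int((view == t).sum(axis=1).max())


def evaluate_candidate(
    locus: GenomicLocus,
    genome: str,
    criteria: CandidateCriteria | None = None,
) -> HairpinCandidate:
    """Fold both arm placements of a locus and apply the hairpin criteria.

    The dominant tag is taken as the putative mature.  Criteria are applied
    in a fixed order and the first failure is recorded; evaluation is fully
    deterministic.  Loci at a contig edge get truncated flanks (not fatal).
    """
    crit = criteria or CandidateCriteria()
    tag, _count, hit_pos = locus.dominant()
    results: list[HairpinCandidate] = []
    for up, down in ((crit.flank_short, crit.flank_long),
                     (crit.flank_long, crit.flank_short)):
        if locus.strand == "+":
            lo = max(0, hit_pos - up)
            hi = min(len(genome), hit_pos + len(tag) + down)
            window = genome[lo:hi]
            mat_off = hit_pos - lo
        else:
            lo = max(0, hit_pos - down)
            hi = min(len(genome), hit_pos + len(tag) + up)
            window = revcomp(genome[lo:hi])
            mat_off = hi - (hit_pos + len(tag))
        results.append(_evaluate_window(locus, window, mat_off, tag, crit))
    accepted = [r for r in results if r.accepted]
    if accepted:
        return max(accepted, key=lambda r: r.mature_pairs)
    return max(results, key=lambda r: r.mature_pairs)


def _evaluate_window(locus: GenomicLocus, window: str, mat_off: int, mature: str,
                     crit: CandidateCriteria) -> HairpinCandidate:
    L = len(mature)

    def reject(label: str, structure: str = "", score: int = 0,
               pairs: int = 0, arm: str | None = None) -> HairpinCandidate:
        return HairpinCandidate(locus, window, structure or "." * len(window),
                                score, mature, mat_off, arm, pairs, label, False)

    if not (crit.mature_len_range[0] <= L <= crit.mature_len_range[1]):
        return reject("mature_length")
    if _best_wc_duplex(mature, window) < min(crit.min_duplex_wc, L - 2):
        return reject("no_duplex")

    model = crit.resolve_energy_model()
    if model is not None:
        structure, energy = model(window)
        score = int(sum(1 for c in structure if c == "("))
    else:
        structure, score = fold_hairpin(window)
        energy = None
    pt = pair_table(structure)

    # pairings of mature bases to partners outside the mature itself
    m_lo, m_hi = mat_off, mat_off + L
    partners = {i: pt[i] for i in range(m_lo, m_hi)
                if i in pt and not (m_lo <= pt[i] < m_hi)}
    down = sorted(j for j in partners.values() if j >= m_hi)
    up = sorted(j for j in partners.values() if j < m_lo)
    star_side = down if len(down) >= len(up) else up
    arm = "5p" if star_side is down else "3p"

    # the star is the densest run of partners spanning <= mature + bulges:
    # stray long-range pairs do not count towards the duplex
    n_star, w_lo, w_hi = 0, 0, 0
    a = 0
    for b in range(len(star_side)):
        while star_side[b] - star_side[a] + 1 > L + crit.max_bulge:
            a += 1
        if b - a + 1 > n_star:
            n_star, w_lo, w_hi = b - a + 1, star_side[a], star_side[b]

    if L - len(partners) > crit.max_unpaired:
        return reject("unpaired_mature_bases", structure, score, n_star, arm)
    if n_star < crit.min_mature_pairs:
        return reject("few_mature_pairs", structure, score, n_star, arm)
    loop = (w_lo - m_hi) if star_side is down else (m_lo - w_hi - 1)
    if not (crit.loop_range[0] <= loop <= crit.loop_range[1]):
        return reject("loop_size", structure, score, n_star, arm)
    if model is not None:
        if energy > crit.max_energy:
            return reject("low_score", structure, score, n_star, arm)
    elif n_star / L < crit.min_paired_frac:
        return reject("low_score", structure, score, n_star, arm)

    return HairpinCandidate(locus, window, structure, score, mature, mat_off,
                            arm, n_star, "accepted", True)


def call_novel_mirnas(
    candidates: dict[str, list[HairpinCandidate]],
    libraries: dict[str, TagLibrary] | None = None,
    window_slack: int = 2,
) -> tuple[list[NovelMiRNA], dict[str, int]]:
    """Merge accepted candidates across libraries and name them.

    Candidates with the same mature sequence, strand and overlapping loci
    are one novel miRNA; ids ``novel_mir_N`` are assigned in genomic order.
    Per-library counts sum every library tag aligning within ``window_slack``
    nt of the mature on the candidate precursor.
    """
    merged: dict[tuple[str, str], NovelMiRNA] = {}
    phase_hits: dict[tuple[str, str], set[str]] = {}
    for lib_label in sorted(candidates):
        for cand in candidates[lib_label]:
            if not cand.accepted:
                continue
            key = (cand.mature, cand.locus.strand)
            if key not in merged:
                merged[key] = NovelMiRNA("", cand.mature, cand.precursor,
                                         cand.structure, cand.locus)
                phase_hits[key] = set()
            phase_hits[key].add(lib_label)

    ordered = sorted(merged.items(), key=lambda kv: (kv[1].locus.start, kv[0]))
    novel: list[NovelMiRNA] = []
    for n, (key, mir) in enumerate(ordered, start=1):
        mir.id = f"novel_mir_{n}"
        if libraries is not None:
            window = set()
            m_off = mir.precursor.find(mir.mature)
            for s in range(max(0, m_off - window_slack), m_off + window_slack + 1):
                for e in range(m_off + len(mir.mature) - window_slack,
                               min(len(mir.precursor),
                                   m_off + len(mir.mature) + window_slack) + 1):
                    if e - s >= 18:
                        window.add(mir.precursor[s:e])
            for label, lib in libraries.items():
                mir.counts[label] = sum(lib.counts.get(t, 0) for t in window)
        novel.append(mir)

    labels = sorted(candidates)
    venn = {"co_expressed": 0}
    for label in labels:
        venn[f"{label}_specific"] = 0
    for key, mir in ordered:
        libs = phase_hits[key]
        if len(libs) > 1:
            venn["co_expressed"] += 1
        else:
            venn[f"{next(iter(libs))}_specific"] += 1
    for label in labels:
        venn[f"total_{label}"] = venn["co_expressed"] + venn[f"{label}_specific"]
    return novel, venn
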
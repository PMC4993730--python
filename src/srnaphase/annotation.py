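"""Genome mapping, priority annotation and known-miRNA identification.

Every unique tag is mapped to the toy genome by exact full-length matching
on both strands, then assigned exactly one annotation category under the
fixed priority rule

    rRNA-etc (GenBank > Rfam)  >  known miRNA  >  piRNA  >  repeat  >  exon  >  intron

with ``unann`` for tags that hit no annotated feature (or no genome
position at all).  Known-miRNA expression is quantified separately by
aligning tags to the precursor within +/-2 nt of the annotated mature
position, tolerating a configurable number of substitutions.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .preprocess import TagLibrary
from .seq import revcomp
from .synthetic import Feature, KnownMirna, ReferenceBundle

#: Category order of the priority rule (highest first).
PRIORITY = ("rrna_etc", "known_mirna", "pirna", "repeat", "exon", "intron")

_FTYPE_CATEGORY = {
    "rRNA": "rrna_etc",
    "tRNA": "rrna_etc",
    "snRNA": "rrna_etc",
    "snoRNA": "rrna_etc",
    "miRNA_primary_transcript": "known_mirna",
    "miRNA": "known_mirna",
    "piRNA": "pirna",
    "repeat_region": "repeat",
    "exon": "exon",
    "intron": "intron",
}


@dataclass
class ReferenceSet:
    """Reference bundle indexed for annotation queries."""

    genome: str
    tracks: dict[str, list[Feature]]
    mirnas: list[KnownMirna]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def from_bundle(cls, bundle: ReferenceBundle) -> "ReferenceSet":
        tracks: dict[str, list[Feature]] = {c: [] for c in PRIORITY}
        for f in bundle.features:
            cat = _FTYPE_CATEGORY.get(f.ftype)
            if cat:
                tracks[cat].append(f)
        return cls(genome=bundle.genome, tracks=tracks, mirnas=list(bundle.mirnas))

    @classmethod
    def from_dir(cls, refdir: str | Path) -> "ReferenceSet":
        """Load genome FASTA, GFF3 tracks and miRNA FASTA files from disk."""
        refdir = Path(refdir)
        genome = _read_single_fasta(refdir / "genome.fa")
        gff = pd.read_csv(
            refdir / "annotations.gff3", sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score", "strand",
                   "frame", "attrs"],
        )
        tracks: dict[str, list[Feature]] = {c: [] for c in PRIORITY}
        for row in gff.itertuples(index=False):
            cat = _FTYPE_CATEGORY.get(row.type)
            if not cat:
                continue
            attrs = dict(kv.split("=", 1) for kv in str(row.attrs).split(";") if "=" in kv)
            tracks[cat].append(Feature(row.seqid, row.source, row.type,
                                       int(row.start) - 1, int(row.end), row.strand,
                                       attrs.get("ID", ""), attrs))
        matures = _read_fasta(refdir / "mirna_mature.fa")
        precursors = {k.removesuffix("_pre"): v
                      for k, v in _read_fasta(refdir / "mirna_precursor.fa").items()}
        mirnas = []
        for mid, mat in matures.items():
            pre = precursors[mid]
            off = pre.find(mat)
            if off < 0:
                raise ValueError(f"mature {mid} not contained in its precursor")
            arm = "3p" if mid.endswith("3p") else "5p"
            mirnas.append(KnownMirna(mid, mat, pre, off, arm, -1, "."))
        return cls(genome=genome, tracks=tracks, mirnas=mirnas)

    def tree(self, category: str) -> IntervalTree:
        if category not in self._trees:
            t = IntervalTree()
            for f in self.tracks.get(category, []):
                t[f.start : f.end] = f
            self._trees[category] = t
        return self._trees[category]


def _read_fasta(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def _read_single_fasta(path: Path) -> str:
    return next(iter(_read_fasta(path).values()))


@dataclass
class AnnotationRecord:
    tag: str
    count: int
    category: str
    feature_id: str | None
    hits: list[tuple[int, str]]


@dataclass
class CompositionTable:
    """Per-category unique-tag and total-read counts with fractions."""

    label: str
    unique: dict[str, int]
    total: dict[str, int]

    def fractions(self, sense: str) -> dict[str, float]:
        data = self.unique if sense == "unique" else self.total
        grand = sum(data.values())
        return {c: (data[c] / grand if grand else 0.0) for c in data}

    def to_frame(self) -> pd.DataFrame:
        cats = list(PRIORITY) + ["unann"]
        fu, ft = self.fractions("unique"), self.fractions("total")
        return pd.DataFrame({
            "category": cats,
            "unique_count": [self.unique.get(c, 0) for c in cats],
            "unique_frac": [round(fu.get(c, 0.0), 6) for c in cats],
            "total_count": [self.total.get(c, 0) for c in cats],
            "total_frac": [round(ft.get(c, 0.0), 6) for c in cats],
        })


def map_tags_to_genome(lib: TagLibrary, genome: str) -> dict[str, list[tuple[int, str]]]:
    """Exact full-length hits of every unique tag, both strands.

    Minus-strand hits are found by locating the reverse complement of the
    tag on the forward genome string; the reported position is the leftmost
    genomic coordinate of the match.
    """
    index: dict[str, list[int]] = defaultdict(list)
    k = 18
    for i in range(len(genome) - k + 1):
        index[genome[i : i + k]].append(i)

    def exact_hits(query: str) -> list[int]:
        return [p for p in index.get(query[:k], ())
                if genome.startswith(query, p)]

    hits: dict[str, list[tuple[int, str]]] = {}
    for tag in lib.counts:
        h = [(p, "+") for p in exact_hits(tag)]
        h += [(p, "-") for p in exact_hits(revcomp(tag))]
        hits[tag] = sorted(h)
    return hits


def annotate_by_priority(
    lib: TagLibrary,
    refs: ReferenceSet,
    hits: dict[str, list[tuple[int, str]]],
) -> tuple[list[AnnotationRecord], CompositionTable]:
    """Assign each unique tag its single highest-priority category.

    A tag matches a category when any of its genome hits overlaps a feature
    of that category (either strand); tags without hits or without any
    feature overlap are ``unann``.  The result is independent of reference
    track input order because categories are probed in the fixed priority
    order.
    """
    records: list[AnnotationRecord] = []
    unique: dict[str, int] = defaultdict(int)
    total: dict[str, int] = defaultdict(int)
    for tag in sorted(lib.counts):
        count = lib.counts[tag]
        tag_hits = hits.get(tag, [])
        category, feat_id = "unann", None
        if tag_hits:
            for cat in PRIORITY:
                tree = refs.tree(cat)
                for pos, _strand in tag_hits:
                    overlaps = tree[pos : pos + len(tag)]
                    if overlaps:
                        category = cat
                        feat_id = sorted(iv.data.feat_id for iv in overlaps)[0]
                        break
                if feat_id is not None:
                    break
        records.append(AnnotationRecord(tag, count, category, feat_id, tag_hits))
        unique[category] += 1
        total[category] += count
    comp = CompositionTable(label=lib.label, unique=dict(unique), total=dict(total))
    return records, comp


def mapped_fraction(lib: TagLibrary, hits: dict[str, list[tuple[int, str]]]) -> dict[str, float]:
    """Fraction of tags with >=1 genome hit, in unique and read senses."""
    mapped_unique = sum(1 for t in lib.counts if hits.get(t))
    mapped_reads = sum(c for t, c in lib.counts.items() if hits.get(t))
    return {
        "unique": mapped_unique / lib.n_unique if lib.n_unique else 0.0,
        "reads": mapped_reads / lib.total_reads if lib.total_reads else 0.0,
    }


def _window_index(refs: ReferenceSet, slack: int = 2) -> dict[str, tuple[int, str]]:
    """Exact lookup of every in-window precursor substring.

    For each mature, all precursor substrings whose start and end lie
    within ``slack`` nt of the mature's boundaries are enumerated; ties on
    identical substrings resolve to the lexicographically smallest miRNA id.
    """
    index: dict[str, tuple[int, str]] = {}
    for m in sorted(refs.mirnas, key=lambda m: m.id):
        lo, hi = m.mat_offset, m.mat_offset + len(m.mature)
        for s in range(max(0, lo - slack), lo + slack + 1):
            for e in range(hi - slack, min(len(m.precursor), hi + slack) + 1):
                if e - s < 18:
                    continue
                sub = m.precursor[s:e]
                if sub not in index:
                    index[sub] = (0, m.id)
    return index


def identify_known_mirnas(
    lib: TagLibrary,
    refs: ReferenceSet,
    max_mismatch: int = 2,
    slack: int = 2,
) -> tuple[dict[str, int], set[str], dict[str, str]]:
    """Quantify known miRNAs; returns (counts, detected set, tag->miRNA map).

    A tag is assigned to a mature miRNA when it aligns to the precursor
    with both ends within ``slack`` nt of the mature's boundaries and at
    most ``max_mismatch`` substitutions (no indels).  Among equally
    mismatched assignments the lexicographically smallest miRNA id wins.
    Counts of all assigned tags are summed per miRNA; a miRNA is detected
    when its count is positive.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    exact = _window_index(refs, slack)

    # 6-mer block prefilter for the substitution search: any alignment with
    # <=2 mismatches over >=18 nt preserves at least one of the three
    # leading 6-mer blocks exactly (pigeonhole).
    kmer_candidates: dict[str, set[int]] = defaultdict(set)
    windows: list[tuple[str, int, int, KnownMirna]] = []
    if max_mismatch > 0:
        for mi, m in enumerate(sorted(refs.mirnas, key=lambda m: m.id)):
            lo = max(0, m.mat_offset - slack)
            hi = min(len(m.precursor), m.mat_offset + len(m.mature) + slack)
            win = m.precursor[lo:hi]
            windows.append((win, lo, mi, m))
            for s in range(len(win) - 5):
                kmer_candidates[win[s : s + 6]].add(mi)

    counts: dict[str, int] = {m.id: 0 for m in refs.mirnas}
    assignment: dict[str, str] = {}
    for tag in sorted(lib.counts):
        hit = exact.get(tag)
        best: tuple[int, str] | None = (0, hit[1]) if hit else None
        if best is None and max_mismatch > 0 and len(tag) >= 18:
            cand = set()
            for s in (0, 6, 12):
                cand |= kmer_candidates.get(tag[s : s + 6], set())
            for mi in sorted(cand):
                win, lo, _, m = windows[mi]
                mstart, mend = m.mat_offset, m.mat_offset + len(m.mature)
                for s in range(max(0, mstart - slack) - lo,
                               max(0, mstart + slack + 1 - lo)):
                    e = s + len(tag)
                    if e > len(win) or not (mend - slack <= lo + e <= mend + slack):
                        continue
                    d = sum(1 for a, b in zip(tag, win[s:e]) if a != b)
                    if d <= max_mismatch and (best is None or (d, m.id) < best):
                        best = (d, m.id)
        if best is not None:
            counts[best[1]] += lib.counts[tag]
            assignment[tag] = best[1]
    detected = {mid for mid, c in counts.items() if c > 0}
    return counts, detected, assignment


def venn_known_mirnas(detected_a: set[str], detected_b: set[str]) -> dict[str, int]:
    """Co-expressed / phase-specific accounting of detected miRNA sets."""
    co = len(detected_a & detected_b)
    a_only = len(detected_a - detected_b)
    b_only = len(detected_b - detected_a)
    return {
        "co_expressed": co,
        "a_specific": a_only,
        "b_specific": b_only,
        "total_a": co + a_only,
        "total_b": co + b_only,
    }


RRNA_QC_THRESHOLDS = {"animal": 0.40, "plant": 0.60}


def rrna_qc_check(comp: CompositionTable, kingdom: str = "animal") -> tuple[bool, float]:
    """Sample-quality check on the total-read rRNA-etc proportion."""
    threshold = RRNA_QC_THRESHOLDS[kingdom]
    proportion = comp.fractions("total").get("rrna_etc", 0.0)
    return proportion < threshold, proportion
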
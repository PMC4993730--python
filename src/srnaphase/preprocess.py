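"""Raw-read cleaning, tag collapsing, length distribution and library overlap.

Raw small-RNA reads are cleaned with six filters applied in a fixed order
(low quality, missing 3' adapter, null insert, 5' adapter contaminant,
poly-A, sub-18-nt insert); each removed read is charged to the *first*
filter it fails, so the per-category counts partition the input exactly.
Survivors are the adapter-trimmed inserts of 18-30 nt; collapsing them
yields the unique-tag count table that every downstream stage consumes.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import (
    DEFAULT_ADAPTER3,
    DEFAULT_ADAPTER5,
    MAX_TAG_LEN,
    MIN_TAG_LEN,
    find_adapter,
    prefix_match,
)

#: Removal categories in filter order (also the Table-style row order).
REMOVAL_CATEGORIES = (
    "low_quality",
    "3adapter_null",
    "insert_null",
    "5adapter_contaminants",
    "smaller_than_18nt",
    "polyA",
)


@dataclass
class RawRead:
    """One raw sequencing read; ``qualities`` are Phred scores (optional)."""

    id: str
    sequence: str
    qualities: list[int] | None = None


@dataclass
class CleaningStats:
    """Per-category read accounting for one library (disjoint categories).

    ``high_quality`` equals ``clean_reads`` plus every adapter/insert/length
    removal category; percentages are reported relative to ``high_quality``.
    """

    total_reads: int = 0
    low_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminants: int = 0
    smaller_than_18nt: int = 0
    polyA: int = 0
    clean_reads: int = 0

    @property
    def high_quality(self) -> int:
        return self.total_reads - self.low_quality

    def percentage(self, count: int) -> float:
        """Percentage of ``high_quality``, rounded to 2 decimals (half-even)."""
        if self.high_quality == 0:
            return 0.0
        return round(100.0 * count / self.high_quality, 2)

    def as_rows(self) -> list[tuple[str, int, float | None]]:
        """Rows in the classification-table layout: (type, count, percent)."""
        return [
            ("Total_reads", self.total_reads, None),
            ("High_quality", self.high_quality, self.percentage(self.high_quality)),
            ("3adapter_null", self.adapter3_null, self.percentage(self.adapter3_null)),
            ("Insert_null", self.insert_null, self.percentage(self.insert_null)),
            ("5adapter_contaminants", self.adapter5_contaminants,
             self.percentage(self.adapter5_contaminants)),
            ("Smaller_than_18nt", self.smaller_than_18nt,
             self.percentage(self.smaller_than_18nt)),
            ("polyA", self.polyA, self.percentage(self.polyA)),
            ("Clean_reads", self.clean_reads, self.percentage(self.clean_reads)),
        ]

    def removal_count(self, category: str) -> int:
        key = {
            "low_quality": "low_quality",
            "3adapter_null": "adapter3_null",
            "insert_null": "insert_null",
            "5adapter_contaminants": "adapter5_contaminants",
            "smaller_than_18nt": "smaller_than_18nt",
            "polyA": "polyA",
        }[category]
        return getattr(self, key)

    def validate(self) -> None:
        removed = sum(self.removal_count(c) for c in REMOVAL_CATEGORIES if c != "low_quality")
        if self.high_quality != self.clean_reads + removed:
            raise ValueError("cleaning accounting violated: high_quality != clean + removed")


@dataclass
class TagLibrary:
    """Collapsed clean tags of one library: unique sequence -> read count."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def to_fasta(self, path: str | Path) -> None:
        """Write collapsed tags as FASTA with ``tagN_xCOUNT`` headers."""
        with open(path, "w") as fh:
            for i, (tag, count) in enumerate(sorted(self.counts.items()), start=1):
                fh.write(f">tag{i}_x{count}\n{tag}\n")

    @classmethod
    def from_fasta(cls, path: str | Path, label: str) -> "TagLibrary":
        counts: dict[str, int] = {}
        header = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    header = line[1:]
                else:
                    count = int(header.rsplit("_x", 1)[1])
                    counts[line] = counts.get(line, 0) + count
        return cls(label=label, counts=counts)


@dataclass
class LengthDistribution:
    """Tag-length histogram, by read or by unique tag."""

    counts: dict[int, int]
    weighting: Literal["by-read", "by-unique-tag"]

    @property
    def fractions(self) -> dict[int, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in sorted(self.counts.items())}

    @property
    def mode(self) -> int:
        return max(sorted(self.counts), key=lambda k: self.counts[k])


@dataclass
class VennSummary:
    """Common/specific tag accounting between two libraries, in both the
    total-read and unique-tag senses."""

    label_a: str
    label_b: str
    common_total_reads: int
    specific_a_total_reads: int
    specific_b_total_reads: int
    common_unique: int
    specific_a_unique: int
    specific_b_unique: int

    @property
    def common_total_pct(self) -> float:
        """Common reads as a percentage of the combined read total."""
        grand = self.common_total_reads + self.specific_a_total_reads + self.specific_b_total_reads
        return round(100.0 * self.common_total_reads / grand, 2) if grand else 0.0

    @property
    def specific_a_unique_pct(self) -> float:
        total_a = self.common_unique + self.specific_a_unique
        return round(100.0 * self.specific_a_unique / total_a, 2) if total_a else 0.0

    @property
    def specific_b_unique_pct(self) -> float:
        total_b = self.common_unique + self.specific_b_unique
        return round(100.0 * self.specific_b_unique / total_b, 2) if total_b else 0.0


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a FASTQ file as :class:`RawRead` records (Phred+33)."""
    with open(path) as fh:
        for rid, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(id=rid.split()[0], sequence=seq.upper(),
                          qualities=[ord(c) - 33 for c in qual])


def classify_read(
    read: RawRead,
    adapter5: str = DEFAULT_ADAPTER5,
    adapter3: str = DEFAULT_ADAPTER3,
    quality_threshold: int = 20,
    max_low_quality_frac: float = 0.1,
) -> tuple[str, str | None]:
    """Classify one read; returns ``(category, trimmed_insert_or_None)``.

    Category is ``"clean"`` or the first failing removal category.  The
    3' adapter must begin within the first ``MAX_TAG_LEN`` bases — a later
    hit cannot delimit a valid 18-30 nt insert and the read is treated as
    adapter-null.
    """
    seq = read.sequence
    if not seq:
        raise ValueError(f"malformed record {read.id!r}: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"malformed record {read.id!r}: invalid characters {sorted(bad)}")

    # 1. low quality: any N, or too many bases below the Phred threshold
    if "N" in seq:
        return "low_quality", None
    if read.qualities is not None:
        n_low = sum(1 for q in read.qualities if q < quality_threshold)
        if n_low > max_low_quality_frac * len(read.qualities):
            return "low_quality", None

    # 2. 3' adapter
    pos = find_adapter(seq, adapter3)
    if pos < 0 or pos > MAX_TAG_LEN:
        return "3adapter_null", None

    # 3. null insert (adapter-adapter ligation)
    if pos == 0:
        return "insert_null", None
    insert = seq[:pos]

    # 4. 5' adapter contaminant
    if prefix_match(insert, adapter5, 0):
        return "5adapter_contaminants", None

    # 5. poly-A insert
    if insert.count("A") >= 0.8 * len(insert):
        return "polyA", None

    # 6. length
    if len(insert) < MIN_TAG_LEN:
        return "smaller_than_18nt", None

    return "clean", insert


def clean_reads(
    reads: Iterable[RawRead],
    adapter5: str = DEFAULT_ADAPTER5,
    adapter3: str = DEFAULT_ADAPTER3,
    quality_threshold: int = 20,
    max_low_quality_frac: float = 0.1,
) -> tuple[list[str], CleaningStats]:
    """Apply the six cleaning filters; return trimmed inserts and accounting.

    Every input read lands in exactly one category (clean or one removal
    bucket), so ``stats`` partitions the input.  Empty input yields empty
    stats, not an error.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    stats = CleaningStats()
    inserts: list[str] = []
    attr = {
        "low_quality": "low_quality",
        "3adapter_null": "adapter3_null",
        "insert_null": "insert_null",
        "5adapter_contaminants": "adapter5_contaminants",
        "smaller_than_18nt": "smaller_than_18nt",
        "polyA": "polyA",
    }
    for read in reads:
        stats.total_reads += 1
        category, insert = classify_read(
            read, adapter5, adapter3, quality_threshold, max_low_quality_frac
        )
        if category == "clean":
            stats.clean_reads += 1
            inserts.append(insert)
        else:
            setattr(stats, attr[category], getattr(stats, attr[category]) + 1)
    stats.validate()
    return inserts, stats


def collapse_tags(inserts: Iterable[str], label: str = "") -> TagLibrary:
    """Collapse cleaned inserts to unique tags with read counts."""
    return TagLibrary(label=label, counts=dict(Counter(inserts)))


def length_distribution(
    lib: TagLibrary, weighting: Literal["by-read", "by-unique-tag"] = "by-read"
) -> LengthDistribution:
    """Tag-length histogram of a library; errors on an empty library."""
    if not lib.counts:
        raise ValueError("length_distribution: empty library")
    counts: Counter[int] = Counter()
    for tag, n in lib.counts.items():
        counts[len(tag)] += n if weighting == "by-read" else 1
    return LengthDistribution(counts=dict(counts), weighting=weighting)


def library_overlap(a: TagLibrary, b: TagLibrary) -> VennSummary:
    """Common/specific tags between two libraries.

    Common-read totals count every read whose tag occurs in both libraries
    (summed over both); percentages are taken against the combined read
    total (total sense) and per-library unique totals (unique sense).
    """
    keys_a, keys_b = set(a.counts), set(b.counts)
    common = keys_a & keys_b
    common_total = sum(a.counts[t] for t in common) + sum(b.counts[t] for t in common)
    spec_a_total = sum(c for t, c in a.counts.items() if t not in common)
    spec_b_total = sum(c for t, c in b.counts.items() if t not in common)
    return VennSummary(
        label_a=a.label,
        label_b=b.label,
        common_total_reads=common_total,
        specific_a_total_reads=spec_a_total,
        specific_b_total_reads=spec_b_total,
        common_unique=len(common),
        specific_a_unique=len(keys_a - common),
        specific_b_unique=len(keys_b - common),
    )


def stats_to_tsv(stats_a: CleaningStats, stats_b: CleaningStats,
                 label_a: str = "Fols", label_b: str = "Luts") -> str:
    """Render two libraries' cleaning stats as the classification table TSV."""
    buf = io.StringIO()
    buf.write(f"Type\t{label_a}_count\t{label_a}_pct\t{label_b}_count\t{label_b}_pct\n")
    for (name, ca, pa), (_, cb, pb) in zip(stats_a.as_rows(), stats_b.as_rows()):
        fa = "" if pa is None else f"{pa:.2f}"
        fb = "" if pb is None else f"{pb:.2f}"
        buf.write(f"{name}\t{ca}\t{fa}\t{cb}\t{fb}\n")
    return buf.getvalue()
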
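"""Synthetic two-phase small-RNA study generator.

Builds a toy reference bundle (genome, annotation tracks, known-miRNA
mature/precursor sets, gene 3'UTRs, GO/KEGG maps) and simulates two raw
FASTQ libraries — a follicular-phase (Fols) and a luteal-phase (Luts)
ovary pool — with fully known ground truth: planted fold-changes on known
miRNAs, planted novel hairpin loci, and contaminant reads engineered to
fail exactly one cleaning filter each.

Counts follow a negative-binomial model (log-normal baseline abundance,
configurable overdispersion); the follicular library acts as the baseline
for the abundance scale, so planted log2 fold-changes are exact on the
mean-count scale.  Clean-read lengths are drawn i.i.d. with a configurable
mode at 22 nt, emulating the Dicer-product peak of real ovary libraries.
Reads are emitted as isomiR-like variants (small 5' offsets, 3'
trimming/extension within the precursor), so each locus yields a family of
recurrent tags dominated by its canonical mature sequence.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seq import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, find_adapter, revcomp

PHASES = ("Fols", "Luts")

#: Mature sequences of real caprine miRNAs used to seed the known set.
SEED_MATURES = [
    ("chi-let-7f-5p", "TGAGGTAGTAGATTGTATAGTT"),
    ("chi-miR-21-5p", "TAGCTTATCAGACTGATGTTGAC"),
    ("chi-miR-10a-5p", "TACCCTGTAGATCCGAATTTGT"),
    ("chi-miR-22-3p", "AAGCTGCCAGTTGAAGAAC"),
    ("chi-miR-125a-5p", "TCCCTGAGACCCTTTAACCTGT"),
]

#: Relative weight of each non-22 clean-tag length (renormalised so that
#: lengths other than 22 share 1 - length_peak_frac of the mass).
_LENGTH_WEIGHTS = {
    18: 2.0, 19: 4.0, 20: 10.0, 21: 14.0, 23: 14.0, 24: 10.0,
    25: 4.0, 26: 2.0, 27: 1.2, 28: 0.8, 29: 0.5, 30: 0.5,
}

_DEFAULT_CONTAMINANT_RATES = {
    # per-read probabilities chosen to emulate the removal-category rates
    # of deep goat ovary libraries (fractions of total raw reads)
    "low_quality": 0.0033,
    "3adapter_null": 0.0038,
    "insert_null": 0.00003,
    "5adapter_contaminant": 0.0003,
    "smaller_than_18nt": 0.008,
    "polyA": 0.00002,
}

_DEFAULT_OTHER_FRACS = {
    # clean-read fractions of the non-miRNA annotation categories; the
    # remainder of each library is miRNA-derived
    "pirna": 0.004,
    "repeat": 0.012,
    "exon": 0.02,
    "intron": 0.08,
    "unann": 0.10,
}


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic generator.

    Defaults describe the emulated study: two deep single-replicate
    libraries (three pooled ovaries per phase), a 22-nt Dicer peak holding
    just under half of the clean reads, removal-category rates below 1 %
    each, and a luteal rRNA fraction several-fold above the follicular one.
    """

    seed: int = 7
    n_reads_per_lib: int = 150_000
    n_known_mirnas: int = 100
    n_novel_loci: int = 8
    frac_de: float = 0.3
    fc_range: tuple[float, float] = (1.0, 3.0)
    frac_specific: float = 0.05
    contaminant_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CONTAMINANT_RATES))
    length_peak_frac: float = 0.48
    genome_len: int = 300_000
    dispersion: float = 0.05
    # clean-read composition (non-miRNA categories); rRNA is per phase
    rrna_fracs: tuple[float, float] = (0.0357, 0.1704)
    other_fracs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_OTHER_FRACS))
    abundance_sigma: float = 1.3
    n_genes: int = 200
    n_go_terms: int = 30
    n_kegg_pathways: int = 15
    n_unann_loci: int = 40
    n_rrna_loci: int = 12
    n_pirna_loci: int = 6
    n_repeat_loci: int = 10
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    read_len: int = 40

    def validate(self) -> None:
        fracs = [self.frac_de, self.frac_specific, self.length_peak_frac,
                 *self.rrna_fracs, *self.other_fracs.values(),
                 *self.contaminant_rates.values()]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(self.contaminant_rates.values()) >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")
        if self.n_reads_per_lib <= 0:
            raise ValueError("n_reads_per_lib must be positive")
        if self.fc_range[0] > self.fc_range[1] or self.fc_range[0] < 0:
            raise ValueError("fc_range must be an increasing pair of magnitudes")


@dataclass
class Feature:
    """One genomic feature; 0-based half-open internally."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    strand: str
    feat_id: str
    attrs: dict[str, str] = field(default_factory=dict)


@dataclass
class KnownMirna:
    id: str
    mature: str
    precursor: str
    mat_offset: int           # 0-based offset of mature within precursor
    arm: str                  # 5p | 3p
    genome_start: int
    strand: str


@dataclass
class NovelLocusTruth:
    id: str
    genome_start: int
    strand: str
    precursor: str            # transcript-orientation stem-loop
    mature: str
    mat_offset: int
    expressed: dict[str, bool] = field(default_factory=dict)


@dataclass
class ReferenceBundle:
    """In-memory reference set; ``write()`` serialises it as plain text."""

    config: SyntheticConfig
    genome: str
    features: list[Feature]
    mirnas: list[KnownMirna]
    novel_loci: list[NovelLocusTruth]
    utrs: dict[str, str]
    go_map: list[tuple[str, str, str]]
    kegg_map: list[tuple[str, str, str]]
    seqid: str = "chr1"

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            fh.write(f">{self.seqid}\n")
            for i in range(0, len(self.genome), 80):
                fh.write(self.genome[i : i + 80] + "\n")
        with open(outdir / "annotations.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for f in self.features:
                attrs = ";".join([f"ID={f.feat_id}"] +
                                 [f"{k}={v}" for k, v in f.attrs.items()])
                fh.write(f"{f.seqid}\t{f.source}\t{f.ftype}\t{f.start + 1}\t{f.end}\t."
                         f"\t{f.strand}\t.\t{attrs}\n")
        with open(outdir / "mirna_mature.fa", "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.id}\n{m.mature}\n")
        with open(outdir / "mirna_precursor.fa", "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.id}_pre {m.id}\n{m.precursor}\n")
        with open(outdir / "utrs.fa", "w") as fh:
            for gene in sorted(self.utrs):
                fh.write(f">{gene}\n{self.utrs[gene]}\n")
        for name, rows in (("go_map.tsv", self.go_map), ("kegg_map.tsv", self.kegg_map)):
            with open(outdir / name, "w") as fh:
                fh.write("gene_id\tterm_id\tterm_name\n")
                for gene, term, term_name in rows:
                    fh.write(f"{gene}\t{term}\t{term_name}\n")
        with open(outdir / "config.yaml", "w") as fh:
            cfg = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(self.config).items()}
            yaml.safe_dump(cfg, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    mirna_lfc: dict[str, float]
    mirna_specific: dict[str, str | None]
    mirna_mu: dict[str, tuple[float, float]]
    mirna_counts: dict[str, tuple[int, int]]
    novel_loci: list[NovelLocusTruth]
    novel_counts: dict[str, tuple[int, int]]
    read_label_counts: dict[str, Counter]
    read_labels: dict[str, dict[str, str]]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_mirna.tsv", "w") as fh:
            fh.write("mirna_id\tlog2_fc\tspecific\tmu_fols\tmu_luts\tcount_fols\tcount_luts\n")
            for mid in sorted(self.mirna_lfc):
                mf, ml = self.mirna_mu[mid]
                cf, cl = self.mirna_counts[mid]
                spec = self.mirna_specific[mid] or "none"
                fh.write(f"{mid}\t{self.mirna_lfc[mid]:.4f}\t{spec}\t"
                         f"{mf:.3f}\t{ml:.3f}\t{cf}\t{cl}\n")
        with open(outdir / "truth_novel.tsv", "w") as fh:
            fh.write("locus_id\tstart\tstrand\tmature\tprecursor\tcount_fols\tcount_luts\n")
            for loc in self.novel_loci:
                cf, cl = self.novel_counts[loc.id]
                fh.write(f"{loc.id}\t{loc.genome_start + 1}\t{loc.strand}\t"
                         f"{loc.mature}\t{loc.precursor}\t{cf}\t{cl}\n")
        with open(outdir / "truth_read_labels.tsv", "w") as fh:
            fh.write("library\tlabel\tcount\n")
            for lib in PHASES:
                for label in sorted(self.read_label_counts[lib]):
                    fh.write(f"{lib}\t{label}\t{self.read_label_counts[lib][label]}\n")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _tag_ok(seq: str, cfg: SyntheticConfig) -> bool:
    """Would this insert survive the cleaning filters unscathed?"""
    if not seq:
        return False
    if cfg.adapter3[:8] in seq:
        return False
    if seq.count("A") >= 0.8 * len(seq):
        return False
    a5 = cfg.adapter5[:8]
    if len(seq) >= 8 and sum(1 for x, y in zip(seq[:8], a5) if x != y) <= 1:
        return False
    return True


def _wobble_star(rng: np.random.Generator, mature: str, n_wobble: int = 2) -> str:
    """Star arm: reverse complement of the mature with G-U wobble edits.

    Interior Watson-Crick pairs are converted to wobbles (C->T opposite G,
    A->G opposite T), so the star sequence differs from the exact reverse
    complement — the mature tag cannot map onto its own star arm on the
    minus strand — while the duplex stays fully base-paired under folding.
    """
    star = list(revcomp(mature))
    eligible = [i for i in range(5, len(star) - 5) if star[i] in "CA"]
    rng.shuffle(eligible)
    for i in eligible[:n_wobble]:
        star[i] = "T" if star[i] == "C" else "G"
    if not eligible:  # degenerate all-G/T interior: fall back to one substitution
        p = len(star) // 2
        star[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[star[p]]
    return "".join(star)


def _hairpin(rng: np.random.Generator, mature: str, arm: str,
             ext: int = 8, loop_len: int = 11) -> tuple[str, int]:
    """Build a stem-loop precursor around ``mature``; returns (seq, offset).

    The star arm is the reverse complement of the mature with wobble
    positions, as in genuine miRNA/miRNA* duplexes.
    """
    star = _wobble_star(rng, mature)
    ext5, ext3, loop = _rand_seq(rng, ext), _rand_seq(rng, ext), _rand_seq(rng, loop_len)
    if arm == "5p":
        seq = ext5 + mature + loop + star + ext3
        offset = ext
    else:
        seq = ext5 + star + loop + mature + ext3
        offset = ext + len(star) + loop_len
    return seq, offset


class _Allocator:
    """Sequential genome-block allocator with randomised inter-feature gaps.

    A padding of at least 120 nt between features guarantees that tags from
    different loci can never be merged by the 50-nt novel-locus clustering.
    """

    def __init__(self, rng: np.random.Generator, genome_len: int, pad: int = 120):
        self.rng = rng
        self.genome_len = genome_len
        self.pad = pad
        self.cursor = 0
        self.blocks: list[tuple[int, int]] = []

    def take(self, length: int) -> int:
        gap = int(self.rng.integers(self.pad, 2 * self.pad))
        start = self.cursor + gap
        end = start + length
        if end > self.genome_len:
            raise ValueError(
                f"genome_len={self.genome_len} too short to place requested features")
        self.cursor = end
        self.blocks.append((start, end))
        return start

    def free_intervals(self, margin: int = 100) -> list[tuple[int, int]]:
        out, prev = [], 0
        for start, end in self.blocks + [(self.genome_len, self.genome_len)]:
            lo, hi = prev + margin, start - margin
            if hi - lo > 40:
                out.append((lo, hi))
            prev = end
        return out


def generate_reference_bundle(cfg: SyntheticConfig) -> ReferenceBundle:
    """Build the toy genome and every reference track, deterministically."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome = bytearray(_rand_seq(rng, cfg.genome_len).encode())
    alloc = _Allocator(rng, cfg.genome_len)
    features: list[Feature] = []
    seqid = "chr1"

    def splice(seq: str, start: int) -> None:
        genome[start : start + len(seq)] = seq.encode()

    # --- known miRNA precursors -----------------------------------------
    matures: list[tuple[str, str]] = []
    for mid, mat in SEED_MATURES[: cfg.n_known_mirnas]:
        matures.append((mid, mat))
    i = 0
    while len(matures) < cfg.n_known_mirnas:
        length = int(rng.choice([21, 22, 23], p=[0.25, 0.5, 0.25]))
        cand = _rand_seq(rng, length)
        if _tag_ok(cand, cfg) and all(cand != m for _, m in matures):
            matures.append((f"chi-miR-s{i:03d}-5p", cand))
            i += 1

    mirnas: list[KnownMirna] = []
    for mid, mat in matures:
        arm = "3p" if mid.endswith("3p") else "5p"
        pre, offset = _hairpin(rng, mat, arm)
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = alloc.take(len(pre))
        splice(pre if strand == "+" else revcomp(pre), gstart)
        mirnas.append(KnownMirna(mid, mat, pre, offset, arm, gstart, strand))
        features.append(Feature(seqid, "mirbase", "miRNA_primary_transcript",
                                gstart, gstart + len(pre), strand, f"{mid}_pre",
                                {"Name": f"{mid}_pre"}))

    # --- novel hairpin loci ---------------------------------------------
    novel: list[NovelLocusTruth] = []
    for j in range(cfg.n_novel_loci):
        while True:
            # GC-clamped ends keep the planted duplex termini from fraying
            mat = ("G" if rng.random() < 0.5 else "C") + _rand_seq(rng, 20) \
                + ("C" if rng.random() < 0.5 else "G")
            if _tag_ok(mat, cfg):
                break
        pre, offset = _hairpin(rng, mat, "5p", ext=0, loop_len=12)
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = alloc.take(len(pre))
        splice(pre if strand == "+" else revcomp(pre), gstart)
        novel.append(NovelLocusTruth(f"planted_novel_{j + 1}", gstart, strand,
                                     pre, mat, offset))

    # --- rRNA-etc / piRNA / repeat tracks -------------------------------
    for k in range(cfg.n_rrna_loci):
        length = int(rng.integers(80, 150))
        start = alloc.take(length)
        source = "GenBank" if k % 2 == 0 else "Rfam"
        features.append(Feature(seqid, source, "rRNA", start, start + length,
                                "+" if rng.random() < 0.5 else "-", f"rrna_{k + 1}"))
    for k in range(cfg.n_pirna_loci):
        length = int(rng.integers(26, 32))
        start = alloc.take(length)
        features.append(Feature(seqid, "pirnabank", "piRNA", start, start + length,
                                "+" if rng.random() < 0.5 else "-", f"pirna_{k + 1}"))
    for k in range(cfg.n_repeat_loci):
        length = int(rng.integers(150, 300))
        start = alloc.take(length)
        features.append(Feature(seqid, "repeatmasker", "repeat_region", start,
                                start + length, "+" if rng.random() < 0.5 else "-",
                                f"repeat_{k + 1}"))

    # --- genes (exon-intron-exon), 3'UTRs, GO / KEGG maps ----------------
    genes = [f"gene_{g + 1:04d}" for g in range(cfg.n_genes)]
    for gene in genes:
        e1, intr, e2 = (int(rng.integers(50, 80)), int(rng.integers(100, 170)),
                        int(rng.integers(50, 80)))
        start = alloc.take(e1 + intr + e2)
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(Feature(seqid, "toygene", "exon", start, start + e1,
                                strand, f"{gene}.e1", {"gene_id": gene}))
        features.append(Feature(seqid, "toygene", "intron", start + e1,
                                start + e1 + intr, strand, f"{gene}.i1",
                                {"gene_id": gene}))
        features.append(Feature(seqid, "toygene", "exon", start + e1 + intr,
                                start + e1 + intr + e2, strand, f"{gene}.e2",
                                {"gene_id": gene}))

    utrs: dict[str, str] = {}
    mature_seqs = [m for _, m in matures] + [loc.mature for loc in novel]
    for gene in genes:
        utr = _rand_seq(rng, int(rng.integers(150, 400)))
        if rng.random() < 0.5:
            for _ in range(int(rng.integers(1, 4))):
                m = mature_seqs[rng.integers(0, len(mature_seqs))]
                site = revcomp(m[1:8])
                if rng.random() < 0.5:
                    site += "A"        # 8mer site: A opposite miRNA position 1
                p = int(rng.integers(0, len(utr) - len(site)))
                utr = utr[:p] + site + utr[p + len(site):]
        utrs[gene] = utr

    go_terms = [(f"GO:{7000 + t:07d}", f"go_term_{t + 1}") for t in range(cfg.n_go_terms)]
    kegg_paths = [(f"ko{t + 1:05d}", f"pathway_{t + 1}") for t in range(cfg.n_kegg_pathways)]
    go_map, kegg_map = [], []
    for gene in genes:
        if rng.random() < 0.9:
            for t in sorted(rng.choice(len(go_terms), size=int(rng.integers(1, 4)),
                                       replace=False)):
                go_map.append((gene, *go_terms[t]))
        if rng.random() < 0.8:
            for t in sorted(rng.choice(len(kegg_paths), size=int(rng.integers(1, 3)),
                                       replace=False)):
                kegg_map.append((gene, *kegg_paths[t]))

    genome_str = genome.decode()

    # planted matures must map uniquely; star-arm substitutions make a
    # second (minus-strand) exact hit essentially impossible, but verify
    for loc in novel:
        assert genome_str.count(loc.mature) + genome_str.count(revcomp(loc.mature)) == 1

    bundle = ReferenceBundle(config=cfg, genome=genome_str, features=features,
                             mirnas=mirnas, novel_loci=novel, utrs=utrs,
                             go_map=go_map, kegg_map=kegg_map)
    bundle._free_intervals = alloc.free_intervals()  # used by simulate_libraries
    return bundle


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _length_probs(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([22] + sorted(_LENGTH_WEIGHTS), dtype=int)
    other = np.array([_LENGTH_WEIGHTS[l] for l in lengths[1:]], dtype=float)
    probs = np.concatenate(([cfg.length_peak_frac],
                            (1.0 - cfg.length_peak_frac) * other / other.sum()))
    return lengths, probs


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=int)
    pos = mu > 0
    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu[pos])
        out[pos] = rng.negative_binomial(r, p)
    else:
        out[pos] = rng.poisson(mu[pos])
    return out


class _VariantEmitter:
    """Emit isomiR-like reads from a precursor-anchored mature sequence."""

    def __init__(self, cfg: SyntheticConfig, rng: np.random.Generator,
                 template: str, mat_offset: int, mature_len: int):
        self.cfg = cfg
        self.rng = rng
        self.template = template
        self.mat_offset = mat_offset
        self.canonical = template[mat_offset : mat_offset + mature_len]
        self.lengths, self.length_probs = _length_probs(cfg)
        self._cache: dict[tuple[int, int], str | None] = {}

    def _variant(self, delta: int, length: int) -> str | None:
        key = (delta, length)
        if key not in self._cache:
            start = max(0, self.mat_offset + delta)
            if start + length > len(self.template):
                start = max(0, len(self.template) - length)
            seq = self.template[start : start + length]
            self._cache[key] = seq if (len(seq) >= 18 and _tag_ok(seq, self.cfg)) else None
        return self._cache[key]

    def emit(self, count: int) -> list[str]:
        if count <= 0:
            return []
        lengths = self.rng.choice(self.lengths, size=count, p=self.length_probs)
        deltas = self.rng.choice([-1, 0, 1], size=count, p=[0.15, 0.7, 0.15])
        reads = []
        for (d, l), k in Counter(zip(deltas.tolist(), lengths.tolist())).items():
            seq = self._variant(d, l) or self.canonical
            reads.extend([seq] * k)
        return reads


def simulate_libraries(
    cfg: SyntheticConfig, bundle: ReferenceBundle, outdir: str | Path | None = None
) -> tuple[dict[str, list[tuple[str, str, str]]], GroundTruth]:
    """Simulate the two raw libraries; optionally write FASTQ files.

    Returns ``(reads, truth)`` where ``reads[lib]`` is a list of
    ``(read_id, sequence, quality)`` tuples in randomized order.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 211])
    lengths_all, length_probs = _length_probs(cfg)
    contam_keys = ["low_quality", "3adapter_null", "insert_null",
                   "5adapter_contaminant", "smaller_than_18nt", "polyA"]

    # ---- planted miRNA truth -------------------------------------------
    n_mir = len(bundle.mirnas)
    ids = [m.id for m in bundle.mirnas]
    abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n_mir)
    order = rng.permutation(n_mir)
    n_spec = round(cfg.frac_specific * n_mir)
    n_de = round(cfg.frac_de * n_mir)
    spec_idx = order[:n_spec]
    de_idx = order[n_spec : n_spec + n_de]
    lfc = np.zeros(n_mir)
    lfc[de_idx] = (rng.uniform(cfg.fc_range[0], cfg.fc_range[1], size=n_de)
                   * rng.choice([-1.0, 1.0], size=n_de))
    specific: dict[str, str | None] = {mid: None for mid in ids}
    for k, idx in enumerate(spec_idx):
        specific[ids[idx]] = PHASES[k % 2]

    contam_total = sum(cfg.contaminant_rates.values())
    clean_target = cfg.n_reads_per_lib * (1.0 - contam_total)
    other_total = sum(cfg.other_fracs.values())

    mu = {}
    for p, lib in enumerate(PHASES):
        mirna_target = clean_target * (1.0 - cfg.rrna_fracs[p] - other_total)
        expressed = np.array([specific[m] in (None, lib) for m in ids])
        if p == 0:
            scale = mirna_target / abundance[expressed].sum()
        mu_lib = scale * abundance * expressed
        if p == 1:
            mu_lib = mu_lib * np.exp2(lfc)
        mu[lib] = mu_lib

    truth = GroundTruth(
        mirna_lfc={mid: float(lfc[i]) for i, mid in enumerate(ids)},
        mirna_specific=specific,
        mirna_mu={mid: (float(mu["Fols"][i]), float(mu["Luts"][i]))
                  for i, mid in enumerate(ids)},
        mirna_counts={},
        novel_loci=bundle.novel_loci,
        novel_counts={},
        read_label_counts={lib: Counter() for lib in PHASES},
        read_labels={lib: {} for lib in PHASES},
    )

    # ---- novel-locus expression pattern --------------------------------
    novel_mu = {}
    for loc in bundle.novel_loci:
        pattern = rng.choice(["both", "Fols", "Luts"], p=[0.4, 0.3, 0.3])
        base = rng.lognormal(mean=math.log(250.0), sigma=0.7)
        loc.expressed = {lib: pattern in ("both", lib) for lib in PHASES}
        novel_mu[loc.id] = {lib: base * loc.expressed[lib] * rng.lognormal(0, 0.2)
                            for lib in PHASES}

    # ---- shared non-miRNA source anchors (common tags across phases) ----
    def track(cat_types: tuple[str, ...]) -> list[Feature]:
        return [f for f in bundle.features if f.ftype in cat_types]

    category_feats = {
        "rrna_etc": track(("rRNA",)),
        "pirna": track(("piRNA",)),
        "repeat": track(("repeat_region",)),
        "exon": track(("exon",)),
        "intron": track(("intron",)),
    }
    anchors: dict[str, list[tuple[int, str, int]]] = {}  # cat -> (pos, strand, room)
    for cat, feats in category_feats.items():
        cat_anchors = []
        for f in feats:
            n_anchor = 1 if f.end - f.start < 80 else 2
            for _ in range(n_anchor):
                room = f.end - f.start
                pos = f.start if room <= 34 else int(rng.integers(f.start, f.end - 32))
                cat_anchors.append((pos, f.strand, min(room, 30)))
        anchors[cat] = cat_anchors
    free = getattr(bundle, "_free_intervals", None) or [(0, cfg.genome_len)]
    free_len = np.array([hi - lo for lo, hi in free], dtype=float)
    unann_anchors = []
    for _ in range(cfg.n_unann_loci):
        seg = rng.choice(len(free), p=free_len / free_len.sum())
        lo, hi = free[seg]
        pos = int(rng.integers(lo, hi - 32))
        unann_anchors.append((pos, "+" if rng.random() < 0.5 else "-", 30))
    anchor_weights = {cat: rng.lognormal(0, 1.0, size=len(a))
                      for cat, a in {**anchors, "unann": unann_anchors}.items()}

    genome = bundle.genome
    emitters = {m.id: _VariantEmitter(cfg, rng, m.precursor, m.mat_offset, len(m.mature))
                for m in bundle.mirnas}
    for loc in bundle.novel_loci:
        window_lo = max(0, loc.genome_start - 2)
        window_hi = min(len(genome), loc.genome_start + len(loc.precursor) + 2)
        segment = genome[window_lo:window_hi]
        template = segment if loc.strand == "+" else revcomp(segment)
        mat_off = template.find(loc.mature)
        emitters[loc.id] = _VariantEmitter(cfg, rng, template, mat_off, len(loc.mature))

    def anchor_reads(pos: int, strand: str, room: int, count: int) -> list[str]:
        reads = []
        lens = rng.choice(lengths_all, size=count, p=length_probs)
        jit = rng.choice([-1, 0, 1], size=count, p=[0.15, 0.7, 0.15])
        for (d, l), k in Counter(zip(jit.tolist(), lens.tolist())).items():
            l = min(l, room) if room >= 18 else 18
            s = max(0, pos + d)
            seq = genome[s : s + l]
            if strand == "-":
                seq = revcomp(seq)
            if not _tag_ok(seq, cfg):
                seq = genome[pos : pos + min(22, room)]
                seq = revcomp(seq) if strand == "-" else seq
                if not _tag_ok(seq, cfg):
                    continue
            reads.extend([seq] * k)
        return reads

    libraries: dict[str, list[tuple[str, str, str]]] = {}
    for p, lib in enumerate(PHASES):
        records: list[tuple[str, str]] = []  # (sequence-or-raw-read, label)

        # clean miRNA reads
        counts = _nb_counts(rng, mu[lib], cfg.dispersion)
        for i, mid in enumerate(ids):
            truth.mirna_counts.setdefault(mid, [0, 0])
            truth.mirna_counts[mid][p] = int(counts[i])
            records.extend((s, "clean_known_mirna") for s in emitters[mid].emit(int(counts[i])))
        # clean novel reads
        for loc in bundle.novel_loci:
            c = int(_nb_counts(rng, np.array([novel_mu[loc.id][lib]]), cfg.dispersion)[0])
            truth.novel_counts.setdefault(loc.id, [0, 0])
            truth.novel_counts[loc.id][p] = c
            records.extend((s, "clean_novel") for s in emitters[loc.id].emit(c))
        # clean non-miRNA category reads
        cat_targets = {"rrna_etc": clean_target * cfg.rrna_fracs[p],
                       **{c: clean_target * f for c, f in cfg.other_fracs.items()}}
        for cat in sorted(cat_targets):
            anchor_list = unann_anchors if cat == "unann" else anchors[cat]
            w = anchor_weights[cat]
            n_cat = int(round(cat_targets[cat]))
            if n_cat == 0 or not anchor_list:
                continue
            per_anchor = rng.multinomial(n_cat, w / w.sum())
            for (pos, strand, room), k in zip(anchor_list, per_anchor.tolist()):
                records.extend((s, f"clean_{cat}") for s in anchor_reads(pos, strand, room, k))

        # contaminants
        a3, a5, rl = cfg.adapter3, cfg.adapter5, cfg.read_len
        n_contam = {c: int(rng.binomial(cfg.n_reads_per_lib, cfg.contaminant_rates[c]))
                    for c in contam_keys}
        contam_raw: list[tuple[str, str, str]] = []  # (seq, qual, label)
        for _ in range(n_contam["low_quality"]):
            pos = int(rng.integers(0, len(genome) - 22))
            seq = (genome[pos : pos + 22] + a3 + _rand_seq(rng, rl))[:rl]
            contam_raw.append((seq, "#" * rl, "low_quality"))
        for _ in range(n_contam["3adapter_null"]):
            while True:
                seq = _rand_seq(rng, rl)
                if a3[:8] not in seq and "N" not in seq and find_adapter(seq, a3) < 0:
                    break
            contam_raw.append((seq, "I" * rl, "3adapter_null"))
        for _ in range(n_contam["insert_null"]):
            seq = (a3 + _rand_seq(rng, rl))[:rl]
            contam_raw.append((seq, "I" * rl, "insert_null"))
        for _ in range(n_contam["5adapter_contaminant"]):
            seq = (a5 + _rand_seq(rng, 2) + a3)[:rl].ljust(rl, "G")
            contam_raw.append((seq, "I" * rl, "5adapter_contaminant"))
        for _ in range(n_contam["smaller_than_18nt"]):
            while True:
                ins = _rand_seq(rng, int(rng.integers(10, 16)))
                if _tag_ok(ins, cfg):
                    break
            seq = (ins + a3 + _rand_seq(rng, rl))[:rl]
            contam_raw.append((seq, "I" * rl, "smaller_than_18nt"))
        for _ in range(n_contam["polyA"]):
            seq = ("A" * 25 + a3 + _rand_seq(rng, rl))[:rl]
            contam_raw.append((seq, "I" * rl, "polyA"))

        # assemble: clean inserts become insert+adapter reads, high quality
        full: list[tuple[str, str, str]] = []
        for seq, label in records:
            raw = (seq + a3 + _rand_seq(rng, 4))[:rl]
            full.append((raw, "I" * len(raw), label))
        full.extend(contam_raw)
        perm = rng.permutation(len(full))
        out = []
        for k, idx in enumerate(perm.tolist()):
            raw, qual, label = full[idx]
            rid = f"{lib}_{k + 1:07d}"
            out.append((rid, raw, qual))
            truth.read_labels[lib][rid] = label
            truth.read_label_counts[lib][label] += 1
        libraries[lib] = out

    truth.mirna_counts = {k: tuple(v) for k, v in truth.mirna_counts.items()}
    truth.novel_counts = {k: tuple(v) for k, v in truth.novel_counts.items()}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib in PHASES:
            with open(outdir / f"{lib.lower()}.fastq", "w") as fh:
                for rid, seq, qual in libraries[lib]:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        truth.write(outdir)
    return libraries, truth
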
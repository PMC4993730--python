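# Methods

This note documents the models, parameter choices and numerical
conventions behind `srnaphase`, and what the synthetic study does and
does not establish about real data.

## Study design being emulated

The pipeline targets the classic two-library small-RNA comparison: one
deeply sequenced library per biological condition (here the follicular
and luteal phases of the caprine estrous cycle, each a pool of three
ovaries), with no replicates.  All statistics are therefore
*two-library* statistics: the exact test conditions on one library's
count and asks whether the other library's count is consistent with
equal underlying proportions given the two sequencing depths.  Nothing
in the package estimates biological variance across animals — with n=1
per condition that is not identifiable, and significance must be read as
"beyond sequencing-sampling noise", not "reproducible across animals".

## Synthetic data generator

`SyntheticConfig` defaults describe the emulated study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_reads_per_lib` | 150,000 | nominal raw reads per library (the real libraries are ~12 M; the generator keeps every rate and fraction at study scale while shrinking depth so the whole analysis runs in seconds) |
| `n_known_mirnas` | 100 | known miRNAs planted in the toy genome; the first five are real caprine matures (let-7f-5p, miR-21-5p, miR-10a-5p, miR-22-3p, miR-125a-5p) |
| `n_novel_loci` | 8 | novel hairpin loci planted in unannotated regions |
| `frac_de` | 0.30 | fraction of known miRNAs given a planted fold-change |
| `fc_range` | (1, 3) | planted log2 fold-change magnitudes, uniform, random sign |
| `frac_specific` | 0.05 | miRNAs expressed in one phase only |
| `length_peak_frac` | 0.48 | clean reads of exactly 22 nt (the Dicer-product peak; real ovary libraries show ~48 % and ~42 %) |
| `contaminant_rates` | ~0.33 %, 0.38 %, 0.003 %, 0.03 %, 0.8 %, 0.002 % | per-read probabilities of the six removal categories, matching deep ovary library accounting |
| `rrna_fracs` | (3.57 %, 17.04 %) | rRNA-etc share of clean reads per phase (the luteal library is markedly rRNA-richer) |
| `dispersion` | 0.05 | negative-binomial overdispersion of per-miRNA counts |
| `genome_len` | 300 kb | toy genome size |

**Count model.** Per-miRNA baseline abundances are log-normal
(σ = 1.3); the follicular library sets the scale so its expected miRNA
read total matches its composition target, and luteal means are the same
baselines times `2^lfc`.  Counts are negative-binomial with variance
μ + φμ² (φ = `dispersion`).  Poisson sampling alone would understate
library-to-library scatter; φ = 0.05 (count CV ≈ 22 % on top of Poisson)
is a modest technical-plus-residual-biological noise level appropriate
for pooled single libraries.  Because luteal totals are not re-scaled,
planted fold-changes are exact on the mean-count scale, and the
luteal library ends up somewhat deeper whenever up-regulation dominates
— just as real paired libraries differ in depth.

**Reads.** Each emitted read is an isomiR-like variant of its source
sequence: an i.i.d. target length (22 nt with probability
`length_peak_frac`, the remainder spread over 18–30 nt peaked at 20–24)
and a 5' offset in {−1, 0, +1}, realised within the precursor (or the
genomic feature for rRNA/repeat/exon/intron/unannotated source loci).
Contaminants are constructed to fail exactly one cleaning filter, in the
filter order, so cleaning statistics can be checked against planted
counts *exactly*.  Every candidate insert is screened so it cannot
accidentally trip an earlier filter (no internal adapter 8-mers, < 80 %
adenine, no 5'-adapter-like prefix).

**Planted hairpins.** A planted precursor is
`mature + loop(11–12 nt) + star`, where the star is the reverse
complement of the mature with two interior G·U wobble conversions and
the mature carries G/C terminal bases.  The wobbles make the star
sequence differ from the exact reverse complement — so a mature tag
cannot exact-map onto its own star arm on the minus strand — while
leaving the duplex fully base-paired under folding; the GC clamps keep
the helix termini from fraying in MFE structures.  Verified across 30
generator seeds, every planted hairpin passes the default acceptance
criteria.

**What the generator does not model:** sequencing errors, quality-score
profiles beyond a binary low-quality flag, multi-mapping tag families,
repeat subfamilies, ontology-graph structure in the GO/KEGG maps, and
replicates.  Green tests therefore certify the *pipeline arithmetic and
statistics* under a faithful miniature of the study design; they do not
certify robustness to base-calling error or to genomes with substantial
repeat content.

## Cleaning

Filters run in a fixed order — low quality, 3'-adapter-null, null
insert, 5'-adapter contaminant, poly-A, length — and each read is
charged to the first filter it fails, giving the disjoint accounting of
the classification table (percentages are reported against the
high-quality read count, to two decimals, round-half-even).  Choices the
table format leaves open:

- *Low quality*: any `N`, or more than 10 % of bases below Q20
  (configurable).
- *3' adapter*: first occurrence of the adapter's leading 8-mer; an
  exact hit is preferred, else one substitution is tolerated.  The
  adapter must begin by position 30 — later hits cannot delimit a valid
  18–30 nt insert, so such reads count as adapter-null.  A hit at
  position 0 is a null insert (adapter-adapter ligation).
- *5' contaminant*: trimmed insert beginning with ≥ 8 bases of the 5'
  adapter (≤ 1 substitution).
- *Poly-A*: insert with ≥ 80 % adenine.

Since a null insert is an adapter hit at position 0, the adapter search
necessarily starts at the read's first base; a variant that only
searches beyond the minimum insert length could never populate the
null-insert category.

## Annotation and known miRNAs

Genome mapping is exact and full-length on both strands (18-mer prefix
index, then full verification); mismatch tolerance applies only at the
miRNA-reference step, where a tag is assigned to a mature if it aligns
to the precursor with both ends within ±2 nt of the mature's boundaries
and ≤ 2 substitutions, no indels.  Equal-mismatch ties go to the
lexicographically smallest miRNA id.  The substitution search uses a
6-mer block prefilter (pigeonhole: ≤ 2 substitutions over ≥ 18 nt leave
one of the three leading 6-mers intact).  Priority annotation probes
categories in the fixed order, so results are independent of reference
track input order.  Internally all coordinates are 0-based half-open;
GFF3 I/O converts to 1-based inclusive at the file boundary.

## Novel miRNA prediction

Unannotated mapped tags are clustered per strand with a 50-nt maximum
gap.  Each locus's dominant tag is evaluated as a putative mature with
two precursor placements (20 nt upstream/150 nt downstream and the
reverse).  A cheap star-arm scan (best ungapped Watson–Crick match of
the mature's reverse complement in the window, threshold 14) skips
folding of hopeless loci.  Acceptance requires, in order: mature length
18–26 nt; ≤ 4 mature bases without any partner outside the mature; ≥ 16
mature bases paired into a single compact star region (partner span ≤
mature length + 6 — stray long-range pairs do not count); a loop of
3–60 nt between mature and star; and a folding-score criterion.

**Folding.** Two engines stand behind one interface.  The default
(`energy_model="auto"`) uses thermodynamic MFE folding via the ViennaRNA
bindings when importable, with the score criterion MFE ≤ −18 kcal/mol;
otherwise a self-contained Nussinov-style base-pair maximiser (minimum
hairpin loop 3, G·U allowed, deterministic traceback) is used with the
criterion that ≥ 55 % of mature bases pair.  Pure base-pair maximisation
is kept as the library primitive `fold_hairpin` because it is exactly
testable by enumeration, but its optimum is highly degenerate on
~190-nt windows — ties can scatter the mature's partners far from the
true star — so the thermodynamic model is preferred for candidate
evaluation whenever available.  Both engines are deterministic, which
the end-to-end byte-identity checks rely on.

On shuffled-genome control loci the acceptance rate of the full
criteria is ~1–2 % (checked at fixed seed; bound < 5 %).

## Differential expression

The exact test uses *raw integer counts* for x and y.  The formula's
factorials are only defined on counts; the normalised-expression reading
of x and y that sometimes circulates is not well defined, so TPM values
serve only fold-change and the filtering rules.  Evaluation is in
log-space via log-gamma: the shorter tail is summed directly (lower tail
by logsumexp; upper tail by a multiplicative term recurrence truncated
at 1e-16 relative size) and the other tail follows from the complement,
so C + D = 1 + p(y|x) holds to machine precision and Σ_y p(y|x) = 1 is
reproduced to 1e-12.

**Two-sidedness and symmetry.** The reported p doubles the smaller
inclusive tail, capped at 1.  With inclusive tails the two orientations
(condition on x vs condition on y) differ by one pmf term, so a naive
implementation gives a p-value that depends on which library is listed
first.  The package removes that artifact by canonicalising the
conditioning side — the library whose (count, depth) pair is
lexicographically smaller is conditioned on — making
`exact_test(x, y, N1, N2)` exactly equal to `exact_test(y, x, N2, N1)`.
The returned C and D remain the caller-orientation tails.  Under null
simulation (Poisson pairs with equal means, equal depths) the test
rejects ~3 % at α = 0.05: conservative, as expected from doubling a
discrete tail.

Planted-fold-change recovery (sign-correct, p < 0.01, among planted
|log2 FC| ≥ 2 at baseline ≥ 50 TPM) is 100 % at the default seed and
94–100 % across seeds; single misses are negative-binomial tail draws,
the honest cost of a replicate-free design.

Fols is the control and Luts the treatment; fold-change is
log2(treatment/control).  A miRNA whose TPM is zero on exactly one side
receives 0.01 there and a phase-specific flag; a miRNA below 1 TPM on
both sides is excluded as low-expressed before testing.

## Targets and enrichment

Target prediction is canonical seed matching: reverse complement of
miRNA positions 2–8 in the 3'UTR (7mer-m8), upgraded to 8mer when the
UTR base opposite position 1 is adenine; a site-filter hook allows
extended-pairing scoring.  A thermodynamic duplex model was deliberately
not used here — seed matching is self-contained, oracle-testable and
standard in the miRNA target literature.

Enrichment uses the upper-tail hypergeometric probability (scipy's
`hypergeom.sf`), with the background defined as every gene carrying at
least one annotation in the namespace.  GO terms are Bonferroni-corrected
by the number of terms actually tested (m > 0; untested terms are
reported with p = 1 but do not deflate power); KEGG pathways get
Benjamini–Hochberg Q-values (statsmodels).  Significance is corrected
p (or Q) ≤ 0.05.

## Pipeline and reproducibility

`run_pipeline` executes the stages in the canonical order and writes one
flat directory of TSV tables plus a markdown report.  No timestamps
enter any table; all randomness flows from the single configured seed;
every set iteration is sorted — two runs from one configuration are
byte-identical, which the acceptance suite verifies by file comparison.
A SHA-256 hash of the canonicalised configuration is embedded in the
report for provenance, and the per-stage log records input/output record
counts so read conservation can be audited from the log alone.

Problem sizes: the default configuration (150k reads/library, 100 known
miRNAs, 8 novel loci, 300 kb genome) was chosen so a full pipeline run
takes ~10 s and the complete test suite under a minute on one CPU, while
keeping ≥ 10 counts for a 50-TPM miRNA so the exact test operates in the
same regime as at real depth.

## Known limitations and open choices

- Two published unique-tag percentages (the phase-specific sequence
  fractions) have denominators that cannot be reconstructed from any
  published total; this package reports specific-tag percentages against
  per-library unique-tag totals and total-read percentages against the
  combined read total.
- Published known/novel miRNA inventory totals conflict between report
  sections (e.g. co-expressed + specific components vs standalone
  totals); the package treats the component arithmetic
  (total = co-expressed + specific) as definitive.
- The mature/star duplex criteria are a reconstruction of the classic
  single-locus predictor family; the original tool's exact thresholds
  are not published as a specification, so the values here (≥ 16 pairs,
  ≤ 4 unpaired, span slack 6, loop 3–60, MFE ≤ −18 kcal/mol) are
  documented defaults, all configurable via `CandidateCriteria`.
- GO ancestry propagation is not performed; term maps are taken as
  given.
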
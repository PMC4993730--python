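# srnaphase

Comparative small-RNA profiling of two sequencing libraries, built around
the classic follicular-phase vs luteal-phase (Fols vs Luts) goat-ovary
study design: one deep small-RNA library per physiological phase (three
pooled ovaries each, no replicates), compared tag by tag.

The package re-implements that complete analysis as a tested, reusable
pipeline driven by a synthetic-data generator with exact ground truth:

1. **Tag cleaning** — six disjoint filters (low quality, missing 3'
   adapter, null insert, 5' adapter contaminant, poly-A, shorter than
   18 nt), collapse to unique 18–30 nt tags, length distributions,
   common/specific tag accounting between the libraries.
2. **Priority annotation** — exact genome mapping on both strands, one
   category per tag under the rule
   `rRNA-etc > known miRNA > piRNA > repeat > exon > intron` (else
   `unann`), plus the animal-sample rRNA quality check (< 40 %).
3. **Known miRNA identification** — tags aligned to mature positions on
   the precursors within ±2 nt and ≤ 2 substitutions.
4. **Novel miRNA prediction** — unannotated tags clustered into loci,
   folded with asymmetric flanks, and accepted when the mature sits in
   one arm of a compact stem-loop duplex (Mireap-style criteria).
5. **Differential expression** — TPM normalisation
   (`count / clean reads × 10⁶`), the 0.01 zero-substitution and < 1 TPM
   exclusion rules, `log2(treatment/control)` fold-change, and the exact
   two-library test

   ```
   p(y|x) = (N2/N1)^y · (x+y)! / ( x!·y!·(1 + N2/N1)^(x+y+1) )
   ```

   with lower/upper tails C and D and reported p = min(1, 2·min(C, D));
   tiers are *extreme* (p < 0.01) and *significant* (0.01 ≤ p < 0.05).
   The 5S-normalised qPCR quantity `2^−(CT_miRNA − CT_5S)` is included.
6. **Targets and enrichment** — seed-complementarity target prediction
   (7mer-m8 / 8mer) in 3'UTRs, then hypergeometric enrichment
   `P(X ≥ m | N, n, M)` with Bonferroni correction for GO terms and
   Benjamini–Hochberg Q-values for KEGG pathways (cutoff 0.05).

## Worked example

```bash
python examples/07_full_pipeline.py
```

prints (abridged):

```
clean[Fols]: total=33351, clean=32863, unique_tags=5268
known miRNAs detected: 97 (Fols) / 96 (Luts), 93 co-expressed
novel miRNAs called: 8 / 7
differential expression: 109 miRNAs tested, 73 extreme (p<0.01)
planted novel loci recovered: 8/8
```

Reading this: ~98.5 % of raw reads survive cleaning; nearly all of the
100 planted known miRNAs are detected in each phase; every planted novel
hairpin locus that was expressed is recovered (the extra call is a
shared-locus duplicate of a junk cluster); and 73 of 109 tested miRNAs
are differentially expressed at p < 0.01 — the generator plants strong
fold-changes on 30 % of miRNAs plus phase-specific expression, and the
1-vs-1 exact test has high power at these depths.  The other examples
(`examples/01…06`) walk through each stage on small hand-built inputs.

A thin CLI wraps the same library:

```bash
srna-phase all --out run_dir --seed 7        # end-to-end synthetic run
srna-phase de --counts-a a.tsv --counts-b b.tsv --total-a 11546193 --total-b 12013471
srna-phase enrich --candidates genes.txt --map go_map.tsv --method go
```

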
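"""Predict a novel miRNA from a hand-built hairpin locus.

A mature 22-mer is embedded in a stem-loop (its star arm carries two G-U
wobbles, as in real miRNA/miRNA* duplexes) inside a random genome.  The
candidate evaluator extracts the tag with asymmetric flanks, folds the
window, and demands a compact, mostly-paired mature/star duplex across a
short loop.
"""

import numpy as np

from srnaphase import CandidateCriteria, evaluate_candidate, fold_hairpin
from srnaphase.novel import GenomicLocus
from srnaphase.seq import revcomp

rng = np.random.default_rng(8)
mature = "G" + "".join(rng.choice(list("ACGT"), 20)) + "C"
star = list(revcomp(mature))
star[6] = "T" if star[6] == "C" else star[6]          # one wobble position
hairpin = mature + "".join(rng.choice(list("ACGT"), 12)) + "".join(star)
genome = ("".join(rng.choice(list("ACGT"), 300)) + hairpin
          + "".join(rng.choice(list("ACGT"), 300)))

locus = GenomicLocus("chr1", 300, 322, "+", [(mature, 57, 300)])
cand = evaluate_candidate(locus, genome, CandidateCriteria())
print(f"verdict: {cand.verdict} (mature on the {cand.arm} arm, "
      f"{cand.mature_pairs}/{len(mature)} mature bases in the duplex)")

structure, n_pairs = fold_hairpin(hairpin)
print(hairpin)
print(structure)
print(f"base-pair maximisation finds {n_pairs} pairs in the isolated precursor")
# An accepted candidate would be named novel_mir_N and quantified like a
# known miRNA in the downstream differential-expression stage.
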
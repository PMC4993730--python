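"""Seed-match target prediction and hypergeometric enrichment.

A gene is a predicted target when its 3'UTR contains the reverse
complement of miRNA positions 2-8 (7mer-m8; 8mer with an A opposite
position 1).  Enrichment tests each term with P(X >= m) under the
hypergeometric law; GO terms get Bonferroni correction, KEGG pathways
Benjamini-Hochberg Q-values.
"""

from srnaphase import go_enrichment, kegg_enrichment, predict_targets
from srnaphase.enrichment import enrichment_frame
from srnaphase.seq import revcomp

mirna = {"chi-let-7f-5p": "TGAGGTAGTAGATTGTATAGTT"}
site = revcomp("TGAGGTAGTAGATTGTATAGTT"[1:8])
utrs = {
    "gene_a": "CCAA" + site + "A" + "GGCCTT" * 10,   # one 8mer site
    "gene_b": "ACGT" * 30,                           # no site
    "gene_c": site + "GG" + site,                    # two 7mer sites
}
for t in predict_targets(mirna, utrs):
    print(f"{t.mirna_id} -> {t.gene_id}: {t.site_count} site(s), {t.site_classes}")

go_map = ([(f"g{i}", "GO:1", "lipid process") for i in range(4)]
          + [(f"g{i}", "GO:2", "housekeeping") for i in range(20)])
frame = enrichment_frame(go_enrichment(["g0", "g1", "g2"], go_map))
print("\nGO enrichment (candidates g0-g2, term GO:1 annotates g0-g3):")
print(frame.to_string(index=False))
# N = annotated background genes, n = candidates, M = genes on the term,
# m = candidates on the term; 'corrected' is the Bonferroni-adjusted p.
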
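"""Exact-test differential expression between two libraries.

Counts are TPM-normalised (count / clean reads x 10^6); a zero on one
side is revised to 0.01, miRNAs below 1 TPM in both libraries are
excluded, and significance comes from the two-library exact test
p(y|x) with doubled smaller tail.
"""

from srnaphase import de_table, exact_test, qpcr_relative_expression

counts = {
    "let-7f-like": (135_763, 318_048),   # strongly up in the treatment library
    "mir-balanced": (27_000, 28_100),    # essentially unchanged
    "mir-rare": (40, 0),                 # detected on one side only
    "mir-noise": (1, 0),                 # below 1 TPM in both -> excluded
}
table = de_table(counts, n1=11_546_193, n2=12_013_471)
print(table[["mirna_id", "tpm_control", "tpm_treatment", "log2_fc",
             "p_value", "tier", "specific", "excluded"]].to_string(index=False))

c, d, p = exact_test(5, 50, 1_000_000, 1_000_000)
print(f"\nexact test, 5 vs 50 reads at equal depth: p = {p:.3g} "
      f"(lower tail C = {c:.3g}, upper tail D = {d:.3g})")
rel = qpcr_relative_expression(18.0, 20.0)
print(f"qPCR relative level for CT(miRNA)=18 vs CT(5S)=20: {rel:.1f}x the control")
# Tier 'extreme' marks p < 0.01, 'significant' marks 0.01 <= p < 0.05.
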
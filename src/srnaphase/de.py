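"""Differential expression between two sequencing libraries.

Counts are normalised to tags per million (TPM = count / total clean reads
x 10^6).  A miRNA whose TPM is zero in exactly one library is revised to
0.01 on that side (and flagged as phase-specific); one whose TPM is below
1 in both libraries is excluded as low-expressed.  Fold-change is
log2(treatment / control) on the post-substitution TPMs.

Significance uses the classic exact test for a count observed in two
libraries of known depths: conditional on observing x in library 1
(depth N1), the probability of observing y in library 2 (depth N2) is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

i.e. y | x follows a negative-binomial with x+1 successes and success
probability N1/(N1+N2).  The lower tail C sums p(y'|x) for y' <= y, the
upper tail D for y' >= y, and the reported two-sided p-value doubles the
smaller tail (capped at 1).  The test runs on raw integer counts — the
factorials are only defined there — while TPM serves fold-change and
filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

TPM_SCALE = 1_000_000
ZERO_SUBSTITUTE = 0.01
LOW_EXPRESSION_TPM = 1.0


@dataclass
class ExpressionRecord:
    mirna_id: str
    x: int                    # control (Fols) raw count
    y: int                    # treatment (Luts) raw count
    n1: int
    n2: int

    @property
    def tpm_control(self) -> float:
        return normalize_tpm(self.x, self.n1)

    @property
    def tpm_treatment(self) -> float:
        return normalize_tpm(self.y, self.n2)


def normalize_tpm(count: float, total_clean_reads: int) -> float:
    """Tags-per-million normalisation: count / total x 10^6."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean_reads * TPM_SCALE


def substitute_and_filter(
    records: list[ExpressionRecord],
) -> tuple[list[tuple[ExpressionRecord, float, float, bool]], list[tuple[ExpressionRecord, str]]]:
    """Apply the zero-substitution and low-expression rules.

    Returns ``(retained, excluded)``; each retained entry carries the
    post-substitution TPM pair and a phase-specific flag (set when one side
    was zero and got the 0.01 substitute).
    """
    retained, excluded = [], []
    for rec in records:
        tc, tt = rec.tpm_control, rec.tpm_treatment
        if tc < LOW_EXPRESSION_TPM and tt < LOW_EXPRESSION_TPM:
            excluded.append((rec, "low expression"))
            continue
        specific = (tc == 0.0) != (tt == 0.0)
        if tc == 0.0 and tt > 0.0:
            tc = ZERO_SUBSTITUTE
        elif tt == 0.0 and tc > 0.0:
            tt = ZERO_SUBSTITUTE
        retained.append((rec, tc, tt, specific))
    return retained, excluded


def fold_change(treatment_tpm: float, control_tpm: float) -> float:
    """log2(treatment / control); both inputs must be positive."""
    if treatment_tpm <= 0 or control_tpm <= 0:
        raise ValueError("fold_change requires positive post-substitution TPMs")
    return math.log2(treatment_tpm / control_tpm)


def _tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float, float]:
    """Inclusive tail probabilities (C, D) and the pmf p(y|x).

    Evaluated in log-space through log-gamma; whichever tail is shorter is
    summed directly (lower tail via logsumexp over y' <= y, upper tail via
    a multiplicative term recurrence truncated at 1e-16 relative size) and
    the other follows from the complement, so C + D = 1 + p(y|x) exactly.
    """
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log(n1 + n2) - math.log(n1)

    def log_pmf(ys: np.ndarray) -> np.ndarray:
        return (ys * log_r + gammaln(x + ys + 1) - gammaln(x + 1)
                - gammaln(ys + 1) - (x + ys + 1) * log_1pr)

    pmf = float(np.exp(log_pmf(np.array([y], dtype=float)))[0])
    mean_y = (x + 1) * n2 / n1
    if y <= mean_y:
        c = float(np.exp(logsumexp(log_pmf(np.arange(0, y + 1, dtype=float)))))
        d = 1.0 - c + pmf
    else:
        # upper tail: term ratio p(y+1|x)/p(y|x) = (n2/(n1+n2)) (x+y+1)/(y+1)
        q = n2 / (n1 + n2)
        total, term, k = 1.0, 1.0, y
        while True:
            term *= q * (x + k + 1) / (k + 1)
            total += term
            k += 1
            if term < 1e-16 * total:
                break
        d = pmf * total
        c = 1.0 - d + pmf
    c = min(1.0, max(0.0, c))
    d = min(1.0, max(0.0, d))
    return c, d, pmf


def exact_test(x: int, y: int, n1: int, n2: int) -> tuple[float, float, float]:
    """Two-library exact test; returns (C, D, two-sided p).

    ``x`` and ``y`` must be raw integer counts.  C and D are the inclusive
    lower/upper tails of p(y'|x) in the caller's orientation.  The reported
    p doubles the smaller tail, with the conditioning side chosen
    canonically — the library whose ``(count, depth)`` pair is
    lexicographically smaller is conditioned on — so the result is
    invariant under swapping the two libraries (with inclusive tails the
    two orientations otherwise differ by one pmf term).
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(
                f"{name} must be a non-negative integer raw count, got {v!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    c, d, _pmf = _tails(x, y, n1, n2)
    if (y, n2) < (x, n1):
        c2, d2, _ = _tails(y, x, n2, n1)
        p = min(1.0, 2.0 * min(c2, d2))
    else:
        p = min(1.0, 2.0 * min(c, d))
    return c, d, p


def classify_significance(p: float) -> str:
    """Tier a p-value: extreme (p<0.01), significant (0.01<=p<0.05), ns."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.01:
        return "extreme"
    if p < 0.05:
        return "significant"
    return "ns"


def qpcr_relative_expression(ct_mirna: float, ct_5s: float) -> float:
    """Relative expression against the 5S internal control: 2^-(CTmiRNA-CT5S)."""
    if not (math.isfinite(ct_mirna) and math.isfinite(ct_5s)):
        raise ValueError("CT values must be finite")
    return 2.0 ** (-(ct_mirna - ct_5s))


def ratio_band(treatment_tpm: float, control_tpm: float) -> str:
    """Expression-ratio band used for scatter-plot colouring."""
    ratio = treatment_tpm / control_tpm
    if ratio > 2.0:
        return "up"
    if ratio <= 0.5:
        return "down"
    return "mid"


def de_table(
    counts: dict[str, tuple[int, int]],
    n1: int,
    n2: int,
    mirna_class: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Full differential-expression table for a set of miRNAs.

    ``counts`` maps miRNA id to (control count, treatment count); ``n1`` and
    ``n2`` are the clean-read totals of the control and treatment library.
    Excluded (low-expression) miRNAs are kept as rows with ``excluded`` set
    and empty statistics.
    """
    records = [ExpressionRecord(mid, c[0], c[1], n1, n2)
               for mid, c in sorted(counts.items())]
    retained, excluded = substitute_and_filter(records)
    rows = []
    for rec, tc, tt, specific in retained:
        _c, _d, p = exact_test(rec.x, rec.y, n1, n2)
        lfc = fold_change(tt, tc)
        rows.append({
            "mirna_id": rec.mirna_id,
            "class": (mirna_class or {}).get(rec.mirna_id, "known"),
            "count_control": rec.x, "count_treatment": rec.y,
            "tpm_control": round(rec.tpm_control, 4),
            "tpm_treatment": round(rec.tpm_treatment, 4),
            "log2_fc": round(lfc, 4),
            "p_value": p,
            "tier": classify_significance(p),
            "ratio_band": ratio_band(tt, tc),
            "specific": specific,
            "excluded": False, "exclude_reason": "",
        })
    for rec, reason in excluded:
        rows.append({
            "mirna_id": rec.mirna_id,
            "class": (mirna_class or {}).get(rec.mirna_id, "known"),
            "count_control": rec.x, "count_treatment": rec.y,
            "tpm_control": round(rec.tpm_control, 4),
            "tpm_treatment": round(rec.tpm_treatment, 4),
            "log2_fc": float("nan"), "p_value": float("nan"), "tier": "",
            "ratio_band": "", "specific": False,
            "excluded": True, "exclude_reason": reason,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("mirna_id", kind="mergesort").reset_index(drop=True)
    return df
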
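"""Seed-match target prediction and GO/KEGG hypergeometric enrichment.

Target prediction uses canonical seed complementarity: a gene is a target
of a miRNA when its 3'UTR contains at least one site exactly reverse-
complementary to miRNA positions 2-8 (7mer-m8), upgraded to 8mer when the
UTR base opposite miRNA position 1 is an adenine.  A pluggable scoring
hook can re-rank or filter sites.

Enrichment tests each term/pathway with the upper-tail hypergeometric
probability P(X >= m) for N background genes, n candidates, M genes on the
term and m candidates on the term.  GO terms are corrected by Bonferroni
(x number of terms actually tested, i.e. with m > 0); KEGG pathways get
Benjamini-Hochberg Q-values.  Significance is corrected p (or Q) <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .seq import revcomp

ALPHA = 0.05


@dataclass
class TargetPrediction:
    mirna_id: str
    gene_id: str
    positions: list[int]          # 0-based site starts in the UTR
    site_classes: list[str]       # "7mer-m8" or "8mer" per site

    @property
    def site_count(self) -> int:
        return len(self.positions)


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    site_filter: Callable[[str, str, int, str], bool] | None = None,
) -> list[TargetPrediction]:
    """Enumerate all seed-match target sites of each miRNA in each 3'UTR.

    ``site_filter(mirna_id, gene_id, position, site_class)`` may veto
    individual sites (extended-pairing scoring hook).  Overlapping sites
    are all reported.  An empty UTR set yields an empty result.
    """
    out: list[TargetPrediction] = []
    for mid in sorted(mirnas):
        seq = mirnas[mid].upper().replace("U", "T")
        if set(seq) - set("ACGT"):
            raise ValueError(f"invalid miRNA sequence for {mid}")
        if len(seq) < 8:
            continue
        site7 = revcomp(seq[1:8])
        for gene in sorted(utrs):
            utr = utrs[gene].upper().replace("U", "T")
            positions, classes = [], []
            start = utr.find(site7)
            while start >= 0:
                cls = "8mer" if utr[start + 7 : start + 8] == "A" else "7mer-m8"
                if site_filter is None or site_filter(mid, gene, start, cls):
                    positions.append(start)
                    classes.append(cls)
                start = utr.find(site7, start + 1)
            if positions:
                out.append(TargetPrediction(mid, gene, positions, classes))
    return out


@dataclass
class EnrichmentTerm:
    term_id: str
    term_name: str
    namespace: str
    N: int
    n: int
    M: int
    m: int
    p: float
    corrected: float
    significant: bool


def load_term_map(path: str | Path) -> pd.DataFrame:
    """Read a gene->term TSV map (columns gene_id, term_id, term_name)."""
    return pd.read_csv(path, sep="\t", dtype=str)


def _term_table(mapping: pd.DataFrame | Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    if isinstance(mapping, pd.DataFrame):
        df = mapping.copy()
        df.columns = ["gene_id", "term_id", "term_name"]
    else:
        df = pd.DataFrame(list(mapping), columns=["gene_id", "term_id", "term_name"])
    return df.drop_duplicates(["gene_id", "term_id"])


def hypergeom_upper(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) drawing n genes from N of which M carry the annotation."""
    if not (0 <= m <= min(n, M) and M <= N and n <= N):
        raise ValueError("inconsistent hypergeometric parameters")
    return float(hypergeom.sf(m - 1, N, M, n))


def _enrich(
    candidates: Sequence[str],
    mapping,
    namespace: str,
    correction: str,
) -> list[EnrichmentTerm]:
    df = _term_table(mapping)
    background = set(df["gene_id"])
    cand = set(candidates)
    missing = sorted(cand - background)
    if missing:
        raise ValueError(
            f"candidate genes absent from the {namespace} background: {missing}")
    N, n = len(background), len(cand)
    terms = []
    for term_id, grp in df.groupby("term_id", sort=True):
        genes = set(grp["gene_id"])
        M, m = len(genes), len(genes & cand)
        p = hypergeom_upper(N, M, n, m) if m > 0 else 1.0
        terms.append((term_id, grp["term_name"].iloc[0], M, m, p))

    tested = [t for t in terms if t[3] > 0]
    results: list[EnrichmentTerm] = []
    if correction == "bonferroni":
        k = len(tested)
        corrected = {t[0]: min(1.0, t[4] * k) for t in tested}
    else:  # Benjamini-Hochberg
        if tested:
            _rej, q, _a, _b = multipletests([t[4] for t in tested], method="fdr_bh")
            corrected = {t[0]: float(qv) for t, qv in zip(tested, q)}
        else:
            corrected = {}
    for term_id, name, M, m, p in terms:
        corr = corrected.get(term_id, 1.0)
        results.append(EnrichmentTerm(term_id, name, namespace, N, n, M, m, p,
                                      corr, bool(m > 0 and corr <= ALPHA)))
    return results


def go_enrichment(candidates: Sequence[str], go_map) -> list[EnrichmentTerm]:
    """Hypergeometric GO enrichment with Bonferroni correction.

    The background is every gene with at least one GO annotation; terms
    with no candidate gene are reported with p = 1 but do not inflate the
    Bonferroni test count.
    """
    return _enrich(candidates, go_map, "GO", "bonferroni")


def kegg_enrichment(candidates: Sequence[str], kegg_map) -> list[EnrichmentTerm]:
    """Hypergeometric KEGG pathway enrichment with Benjamini-Hochberg Q-values."""
    return _enrich(candidates, kegg_map, "KEGG", "bh")


def enrichment_frame(terms: list[EnrichmentTerm]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term_id": t.term_id, "term_name": t.term_name, "namespace": t.namespace,
        "N": t.N, "n": t.n, "M": t.M, "m": t.m,
        "p_value": t.p, "corrected": t.corrected, "significant": t.significant,
    } for t in terms])
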
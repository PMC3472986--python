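"""Hypergeometric functional enrichment of differentially expressed genes.

Terms play the role of GO terms (flat sets, one of three ontologies) and
pathways the role of KEGG pathways. For a universe of N annotated genes of
which n are differentially expressed, and a term annotating M genes of which
m are differentially expressed, the enrichment p-value is the upper tail

    P(X >= m),  X ~ Hypergeometric(N, M, n).

GO-style results are Bonferroni corrected; pathway-style results carry a
Benjamini-Hochberg Q value. No ontology-graph propagation is performed: a
gene is annotated to exactly the terms listed for it.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ONTOLOGIES = ("biological process", "molecular function", "cellular component")

# exact big-integer enumeration is cheap below this universe size; above it
# the log-gamma path avoids huge intermediates
_EXACT_N_LIMIT = 500


@dataclass
class AnnotationMap:
    """Gene -> term and gene -> pathway assignments.

    gene_terms / gene_pathways map every reference gene id to a (possibly
    empty) set of ids; term_ontology maps each term id to one of the three
    ontologies.
    """

    gene_terms: dict[str, set[str]]
    gene_pathways: dict[str, set[str]] = field(default_factory=dict)
    term_ontology: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        return set().union(*self.gene_terms.values()) if self.gene_terms else set()

    def pathways(self) -> set[str]:
        return set().union(*self.gene_pathways.values()) if self.gene_pathways else set()

    def to_frame(self) -> pd.DataFrame:
        """Long-format (gene, id, kind) table; kind is the ontology or 'pathway'."""
        rows = []
        for gene, terms in sorted(self.gene_terms.items()):
            for t in sorted(terms):
                rows.append((gene, t, self.term_ontology.get(t, "term")))
        for gene, paths in sorted(self.gene_pathways.items()):
            for p in sorted(paths):
                rows.append((gene, p, "pathway"))
        return pd.DataFrame(rows, columns=["gene", "id", "kind"])


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_enrich_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(X >= m).

    N: universe size (annotated genes); n: DEGs in the universe; M: genes
    annotated to the term; m: DEGs annotated to the term. Exact integer
    arithmetic for N <= 500, log-gamma summation otherwise.
    """
    N, n, M, m = int(N), int(n), int(M), int(m)
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters N={N}, n={n}, M={M}")
    if not (0 <= m <= min(n, M)):
        raise ValueError(f"infeasible overlap m={m} for n={n}, M={M}")
    if m == 0:
        return 1.0
    top = min(n, M)
    # the support of X also has a lower bound max(0, n+M-N); values of i below
    # it contribute zero mass either way
    if N <= _EXACT_N_LIMIT:
        num = sum(math.comb(M, i) * math.comb(N - M, n - i) for i in range(m, top + 1))
        return num / math.comb(N, n)
    log_denom = _log_comb(N, n)
    logs = [
        _log_comb(M, i) + _log_comb(N - M, n - i) - log_denom
        for i in range(max(m, n + M - N), top + 1)
    ]
    mx = max(logs)
    return float(min(1.0, math.exp(mx) * sum(math.exp(v - mx) for v in logs)))


def _enrich(gene_sets: dict[str, set[str]], degs) -> pd.DataFrame:
    """Shared per-term counting and p-value computation.

    The universe is restricted to genes carrying at least one annotation of
    the relevant kind; DEGs outside it are dropped (and logged).
    """
    universe = {g for g, s in gene_sets.items() if s}
    degs = set(degs)
    dropped = degs - universe
    if dropped:
        logger.info("dropping %d DEGs without annotation from the universe", len(dropped))
    degs &= universe
    if not degs:
        warnings.warn("empty DEG set after universe restriction; nothing can be enriched")
    N, n = len(universe), len(degs)

    term_genes: dict[str, set[str]] = {}
    for gene, ids in gene_sets.items():
        for t in ids:
            term_genes.setdefault(t, set()).add(gene)

    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        M = len(members)
        m = len(members & degs)
        rows.append((term, N, n, M, m, hypergeom_enrich_p(N, n, M, m)))
    return pd.DataFrame(rows, columns=["term", "N", "n", "M", "m", "p_value"])


def go_enrichment(degs, annotation: AnnotationMap, alpha: float = 0.05) -> pd.DataFrame:
    """Per-term enrichment with Bonferroni correction.

    corrected_p = min(1, p x number of terms tested); a term is enriched when
    corrected_p <= alpha.
    """
    df = _enrich(annotation.gene_terms, degs)
    df.insert(1, "ontology", df["term"].map(lambda t: annotation.term_ontology.get(t, "term")))
    k = len(df)
    df["corrected_p"] = np.minimum(1.0, df["p_value"] * k)
    df["enriched"] = df["corrected_p"] <= alpha
    return df


def pathway_enrichment(degs, annotation: AnnotationMap, q_threshold: float = 0.05) -> pd.DataFrame:
    """Per-pathway enrichment with Benjamini-Hochberg Q values."""
    from .de import bh_fdr

    df = _enrich(annotation.gene_pathways, degs)
    df = df.rename(columns={"term": "pathway"})
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    df["enriched"] = df["q_value"] <= q_threshold if len(df) else []
    return df
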
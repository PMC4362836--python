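"""Per-chromosome functional-term enrichment with gene-family collapse.

Enrichment of a term on a chromosome is scored by the upper-tail
hypergeometric probability of drawing at least the observed number of
term-carrying genes in the chromosome's gene set from the annotated universe,
after reducing each gene family to a single representative per chromosome (so
tandem families cannot masquerade as functional clustering).  Benjamini-
Hochberg step-up control yields q-values, by default within each chromosome's
term list, optionally across all (chromosome, term) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import GeneAnnotation, ValidationError

ALPHA = 0.05
FDR = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    chrom: str
    term: str
    k: int  # genes on chromosome carrying the term
    K: int  # genes on chromosome
    m: int  # genes in universe carrying the term
    M: int  # universe size
    p: float
    q: float
    tier: str  # 'significant' | 'suggestive' | 'ns'


def collapse_gene_families(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """Keep one representative gene per (chromosome, family): smallest gene_id."""
    best: dict[tuple[str, str], GeneAnnotation] = {}
    for g in genes:
        key = (g.chrom, g.family_id)
        if key not in best or g.gene_id < best[key].gene_id:
            best[key] = g
    return sorted(best.values(), key=lambda g: g.gene_id)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _tier(p: float, q: float, alpha: float, fdr: float) -> str:
    if p < alpha and q <= fdr:
        return "significant"
    if p < alpha:
        return "suggestive"
    return "ns"


def enrich_chromosome(
    chrom: str,
    genes: Sequence[GeneAnnotation],
    alpha: float = ALPHA,
    fdr: float = FDR,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term with >=1 gene on ``chrom``.

    ``genes`` is the full (collapsed) universe; q-values are BH-adjusted
    across this chromosome's term list.
    """
    if not genes:
        raise ValidationError("empty gene universe")
    M = len(genes)
    on_chrom = [g for g in genes if g.chrom == chrom]
    K = len(on_chrom)
    term_m: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for g in genes:
        for t in g.terms:
            term_m[t] = term_m.get(t, 0) + 1
    for g in on_chrom:
        for t in g.terms:
            term_k[t] = term_k.get(t, 0) + 1
    terms = sorted(term_k)
    p_values = [
        float(stats.hypergeom.sf(term_k[t] - 1, M, term_m[t], K)) for t in terms
    ]
    q_values = benjamini_hochberg(p_values)
    return [
        EnrichmentResult(
            chrom, t, term_k[t], K, term_m[t], M, p, float(q), _tier(p, q, alpha, fdr)
        )
        for t, p, q in zip(terms, p_values, q_values)
    ]


def enrich_all(
    genes: Sequence[GeneAnnotation],
    alpha: float = ALPHA,
    fdr: float = FDR,
    scope: str = "per_chromosome",
    collapse: bool = True,
) -> list[EnrichmentResult]:
    """Enrichment over every chromosome present in the annotation.

    ``scope='per_chromosome'`` applies BH within each chromosome (mirroring
    per-chromosome uploads to enrichment services); ``scope='global'``
    re-adjusts across all (chromosome, term) pairs, the right choice when the
    question is genome-wide.
    """
    if scope not in {"per_chromosome", "global"}:
        raise ValueError(f"unknown scope {scope!r}")
    universe = collapse_gene_families(genes) if collapse else list(genes)
    if not universe:
        raise ValidationError("empty gene universe")
    chroms = sorted({g.chrom for g in universe})
    results: list[EnrichmentResult] = []
    for chrom in chroms:
        results.extend(enrich_chromosome(chrom, universe, alpha, fdr))
    if scope == "global":
        q = benjamini_hochberg([r.p for r in results])
        results = [
            EnrichmentResult(
                r.chrom, r.term, r.k, r.K, r.m, r.M, r.p, float(qi),
                _tier(r.p, qi, alpha, fdr),
            )
            for r, qi in zip(results, q)
        ]
    return results
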
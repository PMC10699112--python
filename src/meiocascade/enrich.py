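"""Hypergeometric over-representation analysis with BH control."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .diffexpr import adjust_bh

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "EnrichmentRecord",
    "hypergeom_enrich",
    "consensus_terms",
    "enriched_gene_pool",
]


@dataclass
class AnnotationSet:
    """term_id -> (description, members), with an explicit gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(f"term {term!r} has members outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_members(
        cls,
        terms: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ) -> "AnnotationSet":
        tmap = {
            t: ((descriptions or {}).get(t, t), frozenset(members))
            for t, members in terms.items()
        }
        if universe is None:
            uni: set[str] = set()
            for _, members in tmap.values():
                uni |= members
        else:
            uni = set(universe)
        return cls(terms=tmap, universe=frozenset(uni))


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    description: str
    k: int     # overlap
    K: int     # term size
    n: int     # query size
    N_u: int   # universe size
    p_raw: float
    p_adj: float
    enriched: bool


def hypergeom_enrich(
    query: set[str], annotations: AnnotationSet, alpha: float = 0.05
) -> list[EnrichmentRecord]:
    """One-tailed hypergeometric over-representation test per term.

    p = P[X >= k] with X ~ Hypergeom(N_u, K, n); BH adjustment across all
    tested terms; enriched iff p_adj < alpha. Query genes outside the
    universe are dropped with a logged count.
    """
    if not query:
        raise ValueError("query gene set is empty")
    in_universe = query & annotations.universe
    dropped = len(query) - len(in_universe)
    if dropped:
        logger.info("dropped %d query genes outside the annotation universe", dropped)
    if not in_universe:
        raise ValueError("no query gene occurs in the annotation universe")
    N_u = len(annotations.universe)
    n = len(in_universe)

    term_ids = sorted(annotations.terms)
    p_raws = []
    overlaps = []
    for term in term_ids:
        _, members = annotations.terms[term]
        k = len(members & in_universe)
        overlaps.append(k)
        p_raws.append(float(stats.hypergeom.sf(k - 1, N_u, len(members), n)))
    p_adjs = adjust_bh(p_raws)

    records = []
    for term, k, p_raw, p_adj in zip(term_ids, overlaps, p_raws, p_adjs):
        desc, members = annotations.terms[term]
        records.append(
            EnrichmentRecord(
                term_id=term,
                description=desc,
                k=k,
                K=len(members),
                n=n,
                N_u=N_u,
                p_raw=p_raw,
                p_adj=p_adj,
                enriched=p_adj < alpha,
            )
        )
    return records


def consensus_terms(
    run_a: Sequence[EnrichmentRecord], run_b: Sequence[EnrichmentRecord]
) -> set[str]:
    """Terms enriched in both runs."""
    if not run_a or not run_b:
        raise ValueError("both enrichment runs must be nonempty")
    ea = {r.term_id for r in run_a if r.enriched}
    eb = {r.term_id for r in run_b if r.enriched}
    common = ea & eb
    if not common:
        logger.warning("no consensus enriched terms between the two runs")
    return common


def enriched_gene_pool(
    enriched_terms: set[str], annotations: AnnotationSet, query: set[str]
) -> set[str]:
    """Union over enriched terms of (term members intersected with query)."""
    missing = enriched_terms - set(annotations.terms)
    if missing:
        raise KeyError(f"unknown terms: {sorted(missing)[:5]}")
    pool: set[str] = set()
    for term in enriched_terms:
        _, members = annotations.terms[term]
        pool |= members & query
    return pool
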
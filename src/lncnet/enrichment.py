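"""Term-enrichment statistics: Fisher exact / hypergeometric tail and the
conservative EASE variant.

For a query set of size N drawn from a background of size M, a term with K
members in the background and k members overlapping the query has

    fisher_p = P(X >= k),       X ~ Hypergeom(M, K, N)
    ease_p   = P(X >= k - 1)

i.e. the EASE score removes one overlapping member before evaluating the same
upper tail, which penalizes terms supported by a single gene (k <= 1 forces
ease_p = 1).  Terms are user data: any annotation table with an explicit
background works; no ontology structure is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .coexpression import bh_adjust


@dataclass
class AnnotationTable:
    """Term membership sets plus the explicit enrichment background."""

    terms: dict[str, frozenset]
    background: frozenset

    def __post_init__(self) -> None:
        self.terms = {str(t): frozenset(m) for t, m in self.terms.items()}
        self.background = frozenset(self.background)
        for term, members in self.terms.items():
            extra = members - self.background
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the background: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_memberships(
        cls, terms: Mapping[str, Iterable[str]], background: Iterable[str]
    ) -> "AnnotationTable":
        return cls({t: frozenset(m) for t, m in terms.items()}, frozenset(background))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    n_background: int
    n_term: int
    n_query: int
    k_overlap: int
    fold_enrichment: float
    fisher_p: float
    ease_p: float


def ease_score(
    query: Iterable[str], term_members: Iterable[str], background: Iterable[str]
) -> EnrichmentResult:
    """Fisher and EASE upper-tail p-values for one term.

    The query must be a subset of the background (offenders are listed in the
    error).  Both p-values lie in (0, 1] and ease_p >= fisher_p always.
    """
    query = frozenset(query)
    members = frozenset(term_members)
    background = frozenset(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query ids outside the background: {offenders[:10]}")
    members = members & background
    M, K, N = len(background), len(members), len(query)
    k = len(query & members)
    # hypergeom.sf(x) = P(X > x); upper tail P(X >= k) = sf(k - 1)
    fisher_p = float(min(1.0, stats.hypergeom.sf(k - 1, M, K, N)))
    if k <= 1:
        ease_p = 1.0
    else:
        ease_p = float(min(1.0, stats.hypergeom.sf(k - 2, M, K, N)))
    if K > 0 and N > 0 and k > 0:
        fold = (k / N) / (K / M)
    else:
        fold = 0.0
    return EnrichmentResult(
        term_id="", n_background=M, n_term=K, n_query=N, k_overlap=k,
        fold_enrichment=fold, fisher_p=fisher_p, ease_p=ease_p,
    )


def enrich(
    query: Iterable[str],
    table: AnnotationTable,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Ranked enrichment table over every term of an annotation table.

    One row per term with counts, fisher_p, ease_p and (for ``adjust="bh"``)
    BH-adjusted EASE p-values; ``significant`` uses raw ease_p <= alpha by
    default (the conventional EASE cutoff), or the adjusted value when BH is
    requested.  Rows are sorted ascending by ease_p, ties broken by term id.
    An empty query warns and returns an empty table.
    """
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    query = frozenset(query)
    if not query:
        warnings.warn("empty query set; returning empty enrichment table")
        return pd.DataFrame(
            columns=["term_id", "n_background", "n_term", "n_query", "k_overlap",
                     "fold_enrichment", "fisher_p", "ease_p", "significant"]
        )
    rows = []
    for term in sorted(table.terms):
        res = ease_score(query, table.terms[term], table.background)
        rows.append(
            {
                "term_id": term,
                "n_background": res.n_background,
                "n_term": res.n_term,
                "n_query": res.n_query,
                "k_overlap": res.k_overlap,
                "fold_enrichment": res.fold_enrichment,
                "fisher_p": res.fisher_p,
                "ease_p": res.ease_p,
            }
        )
    df = pd.DataFrame(rows)
    if adjust == "bh":
        df["ease_p_bh"] = bh_adjust(df["ease_p"].to_numpy())
        df["significant"] = df["ease_p_bh"] <= alpha
    else:
        df["significant"] = df["ease_p"] <= alpha
    return df.sort_values(["ease_p", "term_id"]).reset_index(drop=True)
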
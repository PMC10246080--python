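"""Over-representation baseline: hypergeometric upper-tail test with Bonferroni.

For a sample of n genes drawn from a background of N, a term annotating K
background genes and k sample genes (both under annotation closure) is scored
with P(X >= k), X ~ Hypergeometric(N, K, n). The Bonferroni factor m is the
number of candidate terms actually tested, and ranking is fully deterministic:
(adjusted p, raw p, term id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional

import pandas as pd
from scipy import stats

from .annotations import GeneAnnotationStore, GeneSet
from .errors import MissingGenesError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    k: int
    n_sample: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    rank: int


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a sample of ``n`` from a universe of ``N`` containing
    ``K`` successes. Computed via scipy's log-space survival function, so it
    is stable for large counts.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k} n={n} N={N}")
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    gene_set: GeneSet,
    store: GeneAnnotationStore,
    min_annotated: int = 1,
) -> List[EnrichmentRow]:
    """Hypergeometric over-representation of every candidate term.

    Candidate terms are those with at least ``min_annotated`` sample genes
    under annotation closure. Bonferroni multiplies raw p by the number of
    candidates (capped at 1). Obsolete terms never receive annotations, so
    they are never candidates.
    """
    sample = []
    missing = []
    for g in gene_set.genes:
        canon = store.canonical_symbol(g)
        if canon is None:
            missing.append(g)
        elif canon not in sample:
            sample.append(canon)
    if not sample:
        raise MissingGenesError(gene_set.genes)
    if missing:
        logger.warning(
            "enrich(%s): %d gene(s) not in background: %s",
            gene_set.name, len(missing), ", ".join(missing),
        )
    n = len(sample)
    N = len(store.background)
    sample_set = set(sample)

    # candidate terms: closure-expanded annotations of the sample genes
    counts: dict[str, int] = {}
    for g in sample:
        expanded: set[str] = set()
        for t in store.direct_terms(g):
            expanded |= store.ontology.ancestors(t, reflexive=True)
        for t in expanded:
            counts[t] = counts.get(t, 0) + 1
    candidates = {t: c for t, c in counts.items() if c >= min_annotated}
    if not candidates:
        logger.warning("enrich(%s): no candidate terms under closure", gene_set.name)
        return []
    m = len(candidates)

    scored = []
    for t, k in candidates.items():
        K = len(store.genes_annotated_to(t, store.background))
        p_raw = hypergeom_upper_tail(k, K, n, N)
        scored.append((t, k, K, p_raw, min(1.0, p_raw * m)))
    scored.sort(key=lambda r: (r[4], r[3], r[0]))
    return [
        EnrichmentRow(term=t, k=k, n_sample=n, K=K, N=N, p_raw=p_raw, p_adj=p_adj, rank=i + 1)
        for i, (t, k, K, p_raw, p_adj) in enumerate(scored)
    ]


def enrichment_table(rows: Iterable[EnrichmentRow], store: Optional[GeneAnnotationStore] = None) -> pd.DataFrame:
    """Long-format table of enrichment rows, with labels when a store is given."""
    records = []
    for r in rows:
        label = ""
        if store is not None and r.term in store.ontology:
            label = store.ontology.terms[r.term].label
        records.append(
            {
                "term_id": r.term,
                "term_label": label,
                "rank": r.rank,
                "k": r.k,
                "n": r.n_sample,
                "K": r.K,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["term_id", "term_label", "rank", "k", "n", "K", "N", "p_raw", "p_adj"],
    )
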
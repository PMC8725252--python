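"""Hypergeometric gene-set over-representation of network mRNAs.

For a universe of N genes, a term covering K of them, and a selection of
n genes of which k fall in the term, the enrichment p-value is the
upper-tail hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

i.e. the chance of drawing at least the observed overlap by sampling n
genes without replacement.  The DAVID-style EASE variant, which
substitutes k-1 for k to penalise single-gene overlaps, is available as
a flag; the exact test is the default.  Benjamini-Hochberg q-values are
reported across all tested terms, but raw p drives selection, matching
common microarray-era practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cernet.core_io import GeneSetCollection
from cernet.errors import ValidationError

DEFAULT_ENRICH_P = 0.05
DEFAULT_TOP_N = 30


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    term_name: str
    namespace: str
    N: int
    K: int
    n: int
    k: int
    p_hypergeom: float
    bh_q: float
    fold_enrichment: float
    overlap: frozenset[str]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentRecord]:
    """Test every term of the collection for over-representation.

    ``selected`` must be a subset of ``universe``; term memberships are
    intersected with the universe before testing and terms that vanish
    (K = 0) are dropped.  Records are sorted ascending by p then term id.

    With ``ease=True`` the p-value uses the EASE substitution k -> k-1
    (a conservative DAVID-style score).
    """
    universe = set(universe)
    selected = set(selected)
    offenders = sorted(selected - universe)
    if offenders:
        raise ValidationError(f"selected genes not in universe: {offenders[:10]}")
    N, n = len(universe), len(selected)
    records: list[dict] = []
    for term in collection:
        members = term.members & universe
        K = len(members)
        if K == 0:
            continue
        overlap = frozenset(members & selected)
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_upper_tail(N, K, n, k_eff)
        fold = (k / n) / (K / N) if n else 0.0
        records.append(dict(term_id=term.term_id, term_name=term.term_name,
                            namespace=term.namespace, N=N, K=K, n=n, k=k,
                            p_hypergeom=p, fold_enrichment=fold, overlap=overlap))
    if not records:
        return []
    qs = multipletests([r["p_hypergeom"] for r in records], method="fdr_bh")[1]
    out = [EnrichmentRecord(bh_q=float(q), **r) for r, q in zip(records, qs)]
    out.sort(key=lambda r: (r.p_hypergeom, r.term_id))
    return out


def report_top(
    records: list[EnrichmentRecord],
    p_max: float = DEFAULT_ENRICH_P,
    top_n: int = DEFAULT_TOP_N,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Significant terms (raw p < p_max) truncated to the top ``top_n``.

    Returns the report table and the count of significant terms per
    namespace (counted before truncation).
    """
    significant = [r for r in records if r.p_hypergeom < p_max]
    counts: dict[str, int] = {}
    for r in significant:
        counts[r.namespace] = counts.get(r.namespace, 0) + 1
    top = significant[:top_n]
    table = pd.DataFrame(
        [dict(term_id=r.term_id, term_name=r.term_name, namespace=r.namespace,
              N=r.N, K=r.K, n=r.n, k=r.k, p=r.p_hypergeom, bh_q=r.bh_q,
              fold_enrichment=r.fold_enrichment,
              overlap=",".join(sorted(r.overlap)))
         for r in top],
        columns=["term_id", "term_name", "namespace", "N", "K", "n", "k",
                 "p", "bh_q", "fold_enrichment", "overlap"])
    return table, counts
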
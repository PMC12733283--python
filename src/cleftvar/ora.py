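"""Over-representation analysis of a gene list against gene sets.

The statistic is the standard hypergeometric upper tail: with a background
of N genes of which K belong to a set, and a query of n background genes of
which k overlap the set, the enrichment p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n). Bonferroni adjustment multiplies by the number
of sets tested (FDR is available behind a flag but off by default, matching
the Bonferroni-only convention of the source analysis).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    set_name: str
    N: int
    K: int
    n: int
    k: int
    p: float
    p_adj: float
    significant: bool
    overlap_genes: Tuple[str, ...]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), clipped into (0, 1].

    ``N``: background size, ``K``: set members in background, ``n``: query
    genes in background, ``k``: overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def _normalize(genes: Iterable[str]) -> List[str]:
    seen = {}
    for g in genes:
        key = g.strip().upper()
        if key and key not in seen:
            seen[key] = None
    return list(seen)


def run_ora(
    query_genes: Sequence[str],
    gene_sets: Sequence[Tuple[str, str, Sequence[str]]],
    background: Sequence[str],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> List[EnrichmentResult]:
    """Test each gene set for over-representation of the query.

    Gene symbols are matched case-insensitively. Query genes outside the
    background are dropped (with the survivors re-counted); sets are
    restricted to their background members, and only sets with at least one
    background member are tested — their number is the Bonferroni factor.
    Results are sorted by p ascending (ties by set id).

    ``adjust`` is ``"bonferroni"`` (default) or ``"bh"`` for
    Benjamini-Hochberg step-up FDR.
    """
    if adjust not in ("bonferroni", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    bg = set(_normalize(background))
    if not bg:
        raise ValueError("background is empty")
    query = [g for g in _normalize(query_genes) if g in bg]
    if not query:
        raise ValueError("no query genes remain within the background")
    query_set = set(query)
    N, n = len(bg), len(query)

    testable = []
    for set_id, set_name, genes in gene_sets:
        members = [g for g in _normalize(genes) if g in bg]
        if members:
            testable.append((set_id, set_name, members))
    m = len(testable)

    raw: List[Tuple[str, str, int, int, Tuple[str, ...], float]] = []
    for set_id, set_name, members in testable:
        overlap = tuple(sorted(g for g in members if g in query_set))
        K, k = len(members), len(overlap)
        raw.append((set_id, set_name, K, k, overlap,
                    hypergeom_upper(N, K, n, k)))
    raw.sort(key=lambda r: (r[5], r[0]))

    if adjust == "bonferroni":
        adjusted = [min(1.0, m * p) for *_rest, p in raw]
    else:
        # BH step-up on the p-sorted list
        adjusted = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            p = raw[rank - 1][5]
            running = min(running, p * m / rank)
            adjusted[rank - 1] = running

    return [EnrichmentResult(
        set_id=set_id, set_name=set_name, N=N, K=K, n=n, k=k, p=p,
        p_adj=p_adj, significant=p_adj < alpha, overlap_genes=overlap)
        for (set_id, set_name, K, k, overlap, p), p_adj in zip(raw, adjusted)]
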
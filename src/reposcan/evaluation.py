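"""Validation statistics for a repositioning screen.

Given a scored compound database and an external list of known therapies
for the disease, two questions are asked: are known therapies
over-represented among the significant hits (upper-tail hypergeometric
test), and how early in the ranked output do specific compounds appear
(percentile ranks)?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .ks_core import EnrichmentResult

__all__ = ["EnrichmentCheck", "hypergeometric_enrichment", "percentile_rank"]


@dataclass(frozen=True)
class EnrichmentCheck:
    """Outcome of the known-therapy enrichment test.

    N compounds in the database, K of them known therapies; n_sig compounds
    called significant, k_hit of those known therapies.  ``p_hyper`` is the
    upper-tail probability P(X >= k_hit) under random draws, ``mu`` the
    expected number of known therapies among n_sig random picks.
    """

    N: int
    K: int
    n_sig: int
    k_hit: int
    p_hyper: float
    mu: float


def hypergeometric_enrichment(
    N: int, K: int, n_sig: int, k_hit: int
) -> EnrichmentCheck:
    """Upper-tail hypergeometric test for over-enrichment of known therapies."""
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n_sig <= N):
        raise ValueError(f"need 0 <= n_sig <= N, got n_sig={n_sig}, N={N}")
    if not (0 <= k_hit <= min(K, n_sig)):
        raise ValueError(
            f"need 0 <= k_hit <= min(K, n_sig), got k_hit={k_hit}, "
            f"K={K}, n_sig={n_sig}"
        )
    # P(X >= k_hit) for X ~ Hypergeometric(N, K, n_sig)
    p_upper = float(hypergeom.sf(k_hit - 1, N, K, n_sig))
    p_upper = min(1.0, max(0.0, p_upper))
    mu = n_sig * K / N if N > 0 else 0.0
    return EnrichmentCheck(N=N, K=K, n_sig=n_sig, k_hit=k_hit,
                           p_hyper=p_upper, mu=mu)


def percentile_rank(
    results: Sequence[EnrichmentResult], compound_ids: Iterable[str]
) -> dict[str, float]:
    """Percentile position of requested compounds in the sorted result table.

    ``results`` must already be in screen output order (ascending p with the
    deterministic tie-breaks); the percentile of the compound at 1-based
    rank r among m rows is 100 * r / m, so smaller is better.
    """
    total = len(results)
    if total == 0:
        raise ValueError("empty result table")
    rank_of = {r.compound_id: i + 1 for i, r in enumerate(results)}
    out: dict[str, float] = {}
    for cid in compound_ids:
        if cid not in rank_of:
            raise ValueError(f"compound {cid!r} not present in results")
        out[cid] = 100.0 * rank_of[cid] / total
    return out
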
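"""Signed KS enrichment scoring with a length-stratified bootstrap null.

The statistic compares the ranks that a signature's genes occupy in the
instance against the uniform expectation.  With ``n`` instance genes and a
signature occupying sorted 1-based ranks ``V(1) <= ... <= V(t)``:

    a = max_j [ j/t - V(j)/n ]        (how far ranks run *ahead* of uniform)
    b = max_j [ V(j)/n - (j-1)/t ]    (how far ranks lag *behind* uniform)

    KS = a   if a > b
    KS = -b  otherwise  (including the exact tie a == b)

Positive scores mean the signature's genes concentrate at the top of the
ranking (enrichment); scores near zero or negative mean unenriched or
inversely enriched.  The statistic depends only on the rank positions, so
significance comes from a bootstrap: for each signature length l, score B
uniformly random l-gene subsets of the instance and take the proportion of
resample scores exceeding the observed score.  Nulls are shared across all
signatures of the same length.  p-values are then Benjamini-Hochberg
adjusted across compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .instance_io import RankedInstance
from .signature_db import SignatureDB, restrict_to_instance

logger = logging.getLogger(__name__)

__all__ = [
    "KSScore",
    "NullDistribution",
    "EnrichmentResult",
    "ks_score",
    "bootstrap_null",
    "empirical_p",
    "fdr_adjust",
    "repo",
]

# Cap on elements of the (B, n) uniform matrix used to draw random subsets;
# larger jobs are chunked to bound peak memory.
_CHUNK_ELEMENTS = 20_000_000


@dataclass(frozen=True)
class KSScore:
    """A signed enrichment score with its one-sided components.

    ``a >= 0`` always (its j = t term is ``1 - V(t)/n >= 0``); ``b > 0``
    always (its j = 1 term is ``V(1)/n > 0``); the score is ``a`` when
    ``a > b`` and ``-b`` otherwise.
    """

    value: float
    a: float
    b: float
    t: int
    n: int


@dataclass(frozen=True)
class NullDistribution:
    """Bootstrap KS scores for random signatures of one fixed length."""

    length: int
    scores: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.scores) != self.B:
            raise ValueError("null distribution must hold exactly B scores")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-compound output row: overlap, score, bootstrap p, BH-adjusted q."""

    compound_id: str
    t: int
    ks: float
    p: float
    q: float
    compound_name: str | None = None


def _scores_from_ranks(V: np.ndarray, n: int) -> np.ndarray:
    """Signed KS scores for rows of sorted 1-based ranks, shape (B, t).

    a and b are rationals with denominator t*n, so the a > b decision is
    made in integer arithmetic; float rounding must not flip an exact tie.
    """
    t = V.shape[1]
    Vi = V.astype(np.int64)
    j = np.arange(1, t + 1, dtype=np.int64)
    a_num = (j * n - Vi * t).max(axis=1)
    b_num = (Vi * t - (j - 1) * n).max(axis=1)
    return np.where(a_num > b_num, a_num, -b_num) / float(t * n)


def ks_score(instance: RankedInstance, signature_genes: Iterable[str]) -> KSScore:
    """Score one signature's gene set against the ranked instance.

    The caller restricts the signature first: every gene must be present in
    the instance (a missing gene is a contract violation, not a silent drop).
    """
    genes = set(signature_genes)
    if not genes:
        raise ValueError("empty signature")
    try:
        ranks = sorted(instance.rank_of(g) for g in genes)
    except KeyError as exc:
        raise ValueError(
            f"signature gene {exc.args[0]!r} not in instance; "
            "restrict the signature to the instance first"
        ) from None
    n = instance.n
    t = len(ranks)
    # numerators of a and b over the common denominator t*n: exact integers,
    # so ties (a == b) are decided exactly, never by float rounding
    a_num = max(j * n - v * t for j, v in enumerate(ranks, start=1))
    b_num = max(v * t - (j - 1) * n for j, v in enumerate(ranks, start=1))
    denom = t * n
    a = a_num / denom
    b = b_num / denom
    value = a if a_num > b_num else -b
    return KSScore(value=value, a=a, b=b, t=t, n=n)


def _null_scores(n: int, length: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """KS scores of B uniformly random ``length``-subsets of ranks 1..n."""
    if length == n:
        # every resample is the whole instance: a = 0, b = 1/n, KS = -1/n
        return np.full(B, -1.0 / n)
    out = np.empty(B, dtype=np.float64)
    rows_per_chunk = max(1, _CHUNK_ELEMENTS // n)
    start = 0
    while start < B:
        stop = min(start + rows_per_chunk, B)
        u = rng.random((stop - start, n))
        # the `length` smallest entries per row index a uniform random subset
        idx = np.argpartition(u, length - 1, axis=1)[:, :length]
        V = np.sort(idx, axis=1).astype(np.float64) + 1.0
        out[start:stop] = _scores_from_ranks(V, n)
        start = stop
    return out


def bootstrap_null(
    instance: RankedInstance,
    lengths: Iterable[int],
    B: int = 10_000,
    *,
    seed: int,
) -> dict[int, NullDistribution]:
    """Build one bootstrap null per unique signature length.

    For each unique length l, B gene subsets of size l are drawn uniformly
    without replacement from the instance and scored.  Each length uses an
    independently seeded substream, so the result for a given (seed, l) does
    not depend on which other lengths are requested.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = instance.n
    nulls: dict[int, NullDistribution] = {}
    for length in sorted(set(int(l) for l in lengths)):
        if length < 1:
            raise ValueError("signature length must be >= 1")
        if length > n:
            raise ValueError(f"signature length {length} exceeds instance size {n}")
        rng = np.random.default_rng([seed, length])
        scores = _null_scores(n, length, B, rng)
        nulls[length] = NullDistribution(length=length, scores=scores, B=B, seed=seed)
    return nulls


def empirical_p(
    observed: KSScore, null: NullDistribution, add_one: bool = False
) -> float:
    """Bootstrap p-value: proportion of null scores strictly exceeding the observed.

    The default is the literal proportion, which can be exactly 0; with
    ``add_one`` the standard never-zero estimator ``(count + 1)/(B + 1)`` is
    used instead.  One-sided: only high scores (enrichment) are extreme.
    """
    if null.length != observed.t:
        raise ValueError(
            f"null distribution is for length {null.length}, "
            f"observed signature has t={observed.t}"
        )
    count = int((null.scores > observed.value).sum())
    if add_one:
        return (count + 1) / (null.B + 1)
    return count / null.B


def fdr_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, clipped to 1."""
    arr = np.asarray(p, dtype=np.float64)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def repo(
    instance: RankedInstance,
    db: SignatureDB,
    *,
    B: int = 10_000,
    seed: int,
    min_overlap: int = 1,
    add_one: bool = False,
) -> list[EnrichmentResult]:
    """End-to-end screen: restrict, score, bootstrap, p-values, FDR, sort.

    Results are sorted by ascending p, ties broken by descending KS score,
    then by compound_id, so identical inputs give identical output.
    Signatures removed by restriction are logged, never silently dropped.
    """
    restricted = restrict_to_instance(db, instance, min_overlap=min_overlap)
    dropped = db.n_compounds - restricted.n_compounds
    logger.info(
        "scoring %d signatures (%d dropped for overlap < %d) against %d-gene instance",
        restricted.n_compounds, dropped, min_overlap, instance.n,
    )
    observed = {
        sig.compound_id: ks_score(instance, sig.genes) for sig in restricted
    }
    lengths = {score.t for score in observed.values()}
    nulls = bootstrap_null(instance, lengths, B=B, seed=seed)
    p_by_id = {
        cid: empirical_p(score, nulls[score.t], add_one=add_one)
        for cid, score in observed.items()
    }
    ids = [sig.compound_id for sig in restricted]
    q = fdr_adjust([p_by_id[cid] for cid in ids])
    names = {sig.compound_id: sig.compound_name for sig in restricted}
    results = [
        EnrichmentResult(
            compound_id=cid,
            compound_name=names[cid],
            t=observed[cid].t,
            ks=observed[cid].value,
            p=p_by_id[cid],
            q=float(qv),
        )
        for cid, qv in zip(ids, q)
    ]
    results.sort(key=lambda r: (r.p, -r.ks, r.compound_id))
    return results
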
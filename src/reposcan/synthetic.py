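"""Synthetic instances and signature databases with known ground truth.

Real screens need a ranked disease gene list and a curated compound
database; neither is bundled here.  Instead this module generates both with
controlled structure: instances of ``n`` fake genes in a seeded random
order, null databases of uniformly random signatures, and *planted*
signatures whose genes are concentrated near the top of the ranking with a
tunable strength.  Only rank structure matters to the enrichment statistic,
so no expression values are simulated.

Planting model: a gene's rank is drawn from a discretised Beta(1, c)
distribution over {1..n} (weight proportional to ``(1 - x)^(c-1)`` at the
rank's midpoint x), sampled without replacement.  ``c = 1`` is exactly the
uniform null; large ``c`` pushes all genes toward rank 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .instance_io import RankedInstance
from .signature_db import Signature, SignatureDB

__all__ = [
    "PlantSpec",
    "make_instance",
    "plant_signature",
    "make_null_db",
    "simulate_screen",
]

# A length law is a constant int, an inclusive (lo, hi) uniform range, or an
# explicit {length: weight} mapping.
LengthLaw = int | tuple[int, int] | Mapping[int, float]


@dataclass(frozen=True)
class PlantSpec:
    """How strongly, and at what size, to plant an enriched signature.

    ``concentration`` is the Beta(1, c) strength knob: 1 = uniform null,
    larger = genes packed closer to rank 1.
    """

    t: int
    concentration: float
    seed: int

    def __post_init__(self) -> None:
        if self.t < 1:
            raise ValueError("signature size t must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def make_instance(n: int, seed: int) -> RankedInstance:
    """A ranked instance of ``n`` synthetic genes (``G000001``...).

    Gene labels are shuffled into a seeded random order and given
    p-value-like pseudo-scores that grow with rank (rank 1 is the most
    differentially expressed).
    """
    if n < 1:
        raise ValueError("instance size n must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(6, len(str(n)))
    labels = [f"G{i + 1:0{width}d}" for i in range(n)]
    order = rng.permutation(n)
    scores = np.sort(rng.random(n))
    return RankedInstance(
        genes=tuple(labels[i] for i in order),
        scores=tuple(float(s) for s in scores),
    )


def _rank_weights(n: int, concentration: float) -> np.ndarray:
    x = (np.arange(1, n + 1) - 0.5) / n
    if concentration == 1.0:
        return np.full(n, 1.0 / n)
    # Beta(1, c) density up to normalisation; log-space for large c
    logw = (concentration - 1.0) * np.log1p(-x)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def plant_signature(
    instance: RankedInstance, spec: PlantSpec, compound_id: str = "planted"
) -> Signature:
    """Draw a signature whose gene ranks follow the Beta(1, c) planting law."""
    n = instance.n
    if spec.t > n:
        raise ValueError(f"signature size {spec.t} exceeds instance size {n}")
    rng = np.random.default_rng(spec.seed)
    weights = _rank_weights(n, spec.concentration)
    idx = rng.choice(n, size=spec.t, replace=False, p=weights)
    genes = frozenset(instance.genes[i] for i in idx)
    return Signature(compound_id=compound_id, genes=genes)


def _draw_lengths(
    m: int, length_law: LengthLaw, n: int, rng: np.random.Generator
) -> np.ndarray:
    if isinstance(length_law, int):
        if not (1 <= length_law <= n):
            raise ValueError(f"length {length_law} outside [1, {n}]")
        return np.full(m, length_law, dtype=int)
    if isinstance(length_law, tuple):
        lo, hi = length_law
        if not (1 <= lo <= hi <= n):
            raise ValueError(f"length range ({lo}, {hi}) outside [1, {n}]")
        return rng.integers(lo, hi + 1, size=m)
    lengths = np.array(sorted(length_law.keys()), dtype=int)
    if lengths.min() < 1 or lengths.max() > n:
        raise ValueError(f"length law support outside [1, {n}]")
    probs = np.array([length_law[int(l)] for l in lengths], dtype=float)
    if (probs < 0).any() or probs.sum() <= 0:
        raise ValueError("length law weights must be nonnegative and sum > 0")
    return rng.choice(lengths, size=m, p=probs / probs.sum())


def make_null_db(
    instance: RankedInstance,
    m: int,
    length_law: LengthLaw,
    seed: int,
    id_prefix: str = "C",
) -> SignatureDB:
    """``m`` uniformly random signatures with lengths drawn from ``length_law``."""
    if m < 1:
        raise ValueError("signature count m must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(m, length_law, instance.n, rng)
    width = max(4, len(str(m)))
    sigs = []
    for i, length in enumerate(lengths):
        idx = rng.choice(instance.n, size=int(length), replace=False)
        sigs.append(
            Signature(
                compound_id=f"{id_prefix}{i + 1:0{width}d}",
                genes=frozenset(instance.genes[j] for j in idx),
            )
        )
    return SignatureDB(signatures=tuple(sigs), source=f"synthetic-null(seed={seed})")


def simulate_screen(
    n: int,
    m: int,
    planted: int,
    concentration: float,
    seed: int,
    length_law: LengthLaw = (5, 50),
) -> tuple[RankedInstance, SignatureDB, dict]:
    """A full synthetic screen: instance, database, and ground-truth manifest.

    The database holds ``planted`` enriched signatures (ids ``PLANTED_*``)
    among ``m - planted`` uniformly random ones; all lengths follow
    ``length_law``.  The manifest records the planted compound ids and every
    generation parameter, so a run is reconstructible from it.
    """
    if planted > m:
        raise ValueError("planted signatures cannot exceed total signatures")
    if planted < 0:
        raise ValueError("planted count must be >= 0")
    instance = make_instance(n, seed)
    rng = np.random.default_rng([seed, 1])
    sigs: list[Signature] = []
    planted_ids: list[str] = []
    plant_lengths = _draw_lengths(max(planted, 1), length_law, n, rng)[:planted]
    for i, t in enumerate(plant_lengths):
        cid = f"PLANTED_{i + 1:03d}"
        spec = PlantSpec(t=int(t), concentration=concentration,
                         seed=int(rng.integers(2**31)))
        sigs.append(plant_signature(instance, spec, compound_id=cid))
        planted_ids.append(cid)
    n_null = m - planted
    if n_null:
        null_db = make_null_db(
            instance, n_null, length_law, seed=int(rng.integers(2**31))
        )
        sigs.extend(null_db.signatures)
    manifest = {
        "n_genes": n,
        "n_signatures": m,
        "planted": planted_ids,
        "concentration": concentration,
        "length_law": str(length_law),
        "seed": seed,
    }
    db = SignatureDB(signatures=tuple(sigs), source=f"synthetic-screen(seed={seed})")
    return instance, db, manifest
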
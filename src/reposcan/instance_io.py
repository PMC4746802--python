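"""Reading, identifier-mapping and ordering of disease expression instances.

An *instance* is the complete ranked gene list from one case/control
expression study: every gene measured, ordered by strength of differential
expression, significant or not.  Using all genes — not just a significant
subset — is what guarantees overlap with short compound signatures.

Scores attached to the list are treated as p-value-like by default: a
smaller score means stronger differential expression and hence a better
(lower-numbered) rank.  Effect-size-like scores can be handled by flipping
the sort direction.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "RankedInstance",
    "AliasMap",
    "read_ranked_list",
    "read_alias_map",
    "map_to_entrez",
    "collapse_duplicates",
    "load_instance",
    "write_ranked_list",
]


@dataclass(frozen=True)
class RankedInstance:
    """An ordered list of unique gene identifiers, best rank first.

    Rank positions are 1-based: ``genes[0]`` sits at rank 1.  ``scores``,
    when present, is parallel to ``genes`` and records the ranking score
    each gene carried (dimensionless; smaller = more differentially
    expressed under the default convention).
    """

    genes: tuple[str, ...]
    scores: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError("empty instance")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("instance gene identifiers must be unique")
        if self.scores is not None and len(self.scores) != len(self.genes):
            raise ValueError("genes and scores must have equal length")

    @property
    def n(self) -> int:
        return len(self.genes)

    @cached_property
    def _rank_index(self) -> dict[str, int]:
        return {g: i + 1 for i, g in enumerate(self.genes)}

    def rank_of(self, gene: str) -> int:
        """1-based rank of ``gene``; KeyError if absent."""
        return self._rank_index[gene]

    def __contains__(self, gene: object) -> bool:
        return gene in self._rank_index

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class AliasMap:
    """Many-to-one mapping from alias strings to target identifiers.

    Unmapped aliases are simply absent — an alias never maps to an empty
    string.
    """

    entries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for alias, target in self.entries.items():
            if not str(target).strip():
                raise ValueError(f"alias {alias!r} maps to an empty target")

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, alias: str) -> str | None:
        return self.entries.get(alias)


def _parse_rows(
    path: str | Path, has_header: bool, delimiter: str
) -> list[tuple[str, float | None]]:
    """Parse a 1- or 2-column delimited ranked-list file into (id, score) rows."""
    path = Path(path)
    rows: list[tuple[str, float | None]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, fields in enumerate(reader, start=1):
            if has_header and lineno == 1:
                continue
            if not fields or not "".join(fields).strip():
                continue
            gene = fields[0].strip()
            if len(fields) >= 2 and fields[1].strip() != "":
                try:
                    score: float | None = float(fields[1])
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric score {fields[1]!r} on row {lineno}"
                    ) from None
            else:
                score = None
            rows.append((gene, score))
    if not rows:
        raise ValueError(f"{path}: empty instance")
    return rows


def read_ranked_list(
    path: str | Path,
    has_header: bool = False,
    delimiter: str = "\t",
    descending: bool = False,
) -> RankedInstance:
    """Read a ranked gene list from a delimited text file.

    The file has one gene per row: ``gene_id`` alone, or ``gene_id<delim>score``.
    With a score column, rows are stably sorted by score — ascending by
    default (p-value-like: smaller = stronger), descending with
    ``descending=True`` (effect-size-like).  Without one, file order is the
    ranking.  Duplicate identifiers are collapsed to their best-ranked
    occurrence.
    """
    rows = _parse_rows(path, has_header=has_header, delimiter=delimiter)
    scored = [s is not None for _, s in rows]
    if any(scored) and not all(scored):
        raise ValueError(f"{path}: score column present on some rows but not all")
    if all(scored):
        rows.sort(key=lambda r: -r[1] if descending else r[1])  # type: ignore[operator]
    return collapse_duplicates(rows)


def read_alias_map(path: str | Path, delimiter: str = "\t") -> AliasMap:
    """Read a two-column ``alias<delim>target`` mapping file (no header needed)."""
    entries: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, fields in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not fields or not "".join(fields).strip():
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: row {lineno} needs two columns")
            entries[fields[0].strip()] = fields[1].strip()
    if not entries:
        raise ValueError(f"{path}: empty alias map")
    return AliasMap(entries)


def map_to_entrez(
    raw: Sequence[tuple[str, float | None]], mapping: AliasMap
) -> list[tuple[str, float | None]]:
    """Translate (alias, score) pairs to (target-id, score) pairs.

    Aliases absent from the mapping are dropped (the count is logged);
    input order is preserved.  Raises if nothing maps at all.
    """
    if len(mapping) == 0:
        raise ValueError("empty alias map")
    if not raw:
        raise ValueError("no genes mapped: empty input")
    mapped: list[tuple[str, float | None]] = []
    dropped = 0
    for alias, score in raw:
        target = mapping.get(alias)
        if target is None:
            dropped += 1
        else:
            mapped.append((target, score))
    if dropped:
        logger.info("identifier mapping dropped %d of %d aliases", dropped, len(raw))
    if not mapped:
        raise ValueError("no genes mapped")
    return mapped


def collapse_duplicates(
    mapped: Sequence[tuple[str, float | None]]
) -> RankedInstance:
    """Collapse repeated identifiers, keeping each gene's best-ranked occurrence.

    "Best" is the smallest score when scores are present (ties: earliest
    position), otherwise the earliest position — the strongest evidence for
    that gene.  The retained entries keep their relative order.
    """
    # best[gene] = (score-or-None, position of the retained occurrence)
    best: dict[str, tuple[float | None, int]] = {}
    for pos, (gene, score) in enumerate(mapped):
        if gene not in best:
            best[gene] = (score, pos)
        else:
            old_score, _ = best[gene]
            if score is not None and old_score is not None and score < old_score:
                best[gene] = (score, pos)
    n_dup = len(mapped) - len(best)
    if n_dup:
        logger.info("collapsed %d duplicate entries to best-ranked occurrence", n_dup)
    retained = sorted(best.items(), key=lambda kv: kv[1][1])
    genes = tuple(g for g, _ in retained)
    scores = tuple(s for _, (s, _) in retained)
    if any(s is None for s in scores):
        return RankedInstance(genes=genes)
    return RankedInstance(genes=genes, scores=scores)  # type: ignore[arg-type]


def load_instance(
    path: str | Path,
    mapping: AliasMap | None = None,
    has_header: bool = False,
    delimiter: str = "\t",
    descending: bool = False,
) -> RankedInstance:
    """Full ingest pipeline: parse, optionally alias-map, sort, deduplicate."""
    rows = _parse_rows(path, has_header=has_header, delimiter=delimiter)
    if mapping is not None:
        rows = map_to_entrez(rows, mapping)
    scored = [s is not None for _, s in rows]
    if all(scored) and rows:
        rows.sort(key=lambda r: -r[1] if descending else r[1])  # type: ignore[operator]
    return collapse_duplicates(rows)


def write_ranked_list(
    instance: RankedInstance, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write an instance back to disk in the same 1-/2-column format."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if instance.scores is None:
            for g in instance.genes:
                writer.writerow([g])
        else:
            for g, s in zip(instance.genes, instance.scores):
                writer.writerow([g, repr(s)])
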
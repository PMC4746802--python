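"""Compound-gene signature databases: GMT I/O, CTD conversion, restriction.

A *signature* is an unordered, directionless set of genes known to interact
with one compound.  Directionality of interaction is deliberately ignored
throughout, so that databases with no regulatory annotation (or with
conflicting annotations) can be scored.

Databases travel as Broad-style GMT text (one signature per line:
``name<TAB>description<TAB>gene1<TAB>gene2...``) or are built from a raw
Comparative Toxicogenomics Database (CTD) chemical-gene interactions dump.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pandas as pd

from .instance_io import RankedInstance

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "SignatureDB",
    "read_gmt",
    "write_gmt",
    "convert_ctd",
    "restrict_to_instance",
]


@dataclass(frozen=True)
class Signature:
    """One compound and its unordered set of interacting genes.

    ``t`` is the overlap size with a particular instance; it is set only
    after :func:`restrict_to_instance` and is ``None`` for a raw database.
    """

    compound_id: str
    genes: frozenset[str]
    compound_name: str | None = None
    t: int | None = None

    def __post_init__(self) -> None:
        if self.t is not None and self.t > len(self.genes):
            raise ValueError("overlap t cannot exceed signature size")


@dataclass(frozen=True)
class SignatureDB:
    """A collection of signatures with provenance metadata."""

    signatures: tuple[Signature, ...]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [s.compound_id for s in self.signatures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound identifiers: {dupes[:5]}")

    @property
    def n_compounds(self) -> int:
        return len(self.signatures)

    @property
    def n_genes(self) -> int:
        union: set[str] = set()
        for s in self.signatures:
            union |= s.genes
        return len(union)

    def __len__(self) -> int:
        return self.n_compounds

    def __iter__(self) -> Iterator[Signature]:
        return iter(self.signatures)


def read_gmt(path: str | Path) -> SignatureDB:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line are deduplicated with a logged warning;
    duplicate signature names across lines are an error.
    """
    path = Path(path)
    sigs: list[Signature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields, need >= 3 "
                    "(name, description, genes...)"
                )
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning(
                    "%s: line %d (%s): %d duplicate genes within signature removed",
                    path, lineno, name, len(genes) - len(unique),
                )
            if not unique:
                raise ValueError(f"{path}: line {lineno} ({name}) has no genes")
            sigs.append(
                Signature(
                    compound_id=name,
                    compound_name=None if desc in (".", "", "na") else desc,
                    genes=unique,
                )
            )
    if not sigs:
        raise ValueError(f"{path}: no signatures found")
    return SignatureDB(signatures=tuple(sigs), source=str(path))


def write_gmt(db: SignatureDB, path: str | Path) -> None:
    """Write a database as GMT; genes are emitted in sorted order for stable output.

    ``read_gmt(write_gmt(db))`` reproduces the compound -> gene-set mapping
    exactly.
    """
    if db.n_compounds == 0:
        raise ValueError("cannot write empty signature database")
    with open(path, "w") as fh:
        for sig in db:
            desc = sig.compound_name if sig.compound_name else "."
            fh.write("\t".join([sig.compound_id, desc, *sorted(sig.genes)]) + "\n")


# Logical column -> names accepted in CTD chem_gene_ixns dumps.
_CTD_COLUMNS = {
    "chemical_name": ["ChemicalName"],
    "chemical_id": ["ChemicalID"],
    "gene_id": ["GeneID"],
    "gene_symbol": ["GeneSymbol"],
    "organism_id": ["OrganismID"],
    "pubmed_ids": ["PubMedIDs"],
    "gene_forms": ["GeneForms"],
}


def _open_text(path: Path) -> io.TextIOBase:
    # gzip-transparent: sniff the magic bytes rather than trusting the suffix
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")  # type: ignore[return-value]
    return open(path)


def _ctd_header_and_data(path: Path) -> tuple[list[str], list[str]]:
    """Split a CTD dump into its column names and data lines.

    Two dialects are accepted: a plain first-row header, or CTD's commented
    header block where the last ``#`` line before the data carries the
    column names.
    """
    comment_lines: list[str] = []
    data_lines: list[str] = []
    header: list[str] | None = None
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                comment_lines.append(line.lstrip("# ").rstrip())
                continue
            if header is None:
                fields = line.split("\t")
                if any(f in fields for f in _CTD_COLUMNS["chemical_name"]):
                    header = fields
                    continue
                # no plain header: fall back to the last comment line that
                # looks like a field list
                for cl in reversed(comment_lines):
                    cfields = cl.split("\t")
                    if any(f in cfields for f in _CTD_COLUMNS["chemical_name"]):
                        header = cfields
                        break
                if header is None:
                    raise ValueError(
                        f"{path}: cannot locate a header row naming column "
                        f"'{_CTD_COLUMNS['chemical_name'][0]}'"
                    )
            data_lines.append(line)
    if header is None:
        raise ValueError(f"{path}: no data rows")
    return header, data_lines


def convert_ctd(
    path: str | Path,
    organism_id: str = "9606",
    require_evidence: bool = True,
) -> SignatureDB:
    """Convert a raw CTD chemical-gene interactions dump into a signature database.

    Rows are kept iff the organism taxon matches ``organism_id`` (default
    9606, human) and — when ``require_evidence`` — the PubMed evidence field
    is nonempty, i.e. the interaction is literature-supported.  Kept rows
    are grouped by chemical; each signature is the union of that chemical's
    interacting gene IDs.  All gene forms (gene, mRNA, protein, polypeptide,
    ...) are retained: gene products count as interactions with their gene.
    Interaction directionality is ignored by construction.
    """
    path = Path(path)
    header, data_lines = _ctd_header_and_data(path)

    resolved: dict[str, str] = {}
    for logical, candidates in _CTD_COLUMNS.items():
        for cand in candidates:
            if cand in header:
                resolved[logical] = cand
                break
    required = ["chemical_name", "chemical_id", "gene_id", "organism_id",
                "pubmed_ids", "gene_forms"]
    for logical in required:
        if logical not in resolved:
            raise ValueError(
                f"{path}: required column {_CTD_COLUMNS[logical][0]!r} not found "
                f"in header {header}"
            )

    df = pd.read_csv(
        io.StringIO("\n".join(data_lines)),
        sep="\t", names=header, dtype=str, keep_default_na=False,
    )
    n_total = len(df)
    keep = df[resolved["organism_id"]].str.strip() == str(organism_id)
    if require_evidence:
        keep &= df[resolved["pubmed_ids"]].str.strip() != ""
    df = df[keep]
    if df.empty:
        raise ValueError(
            f"{path}: zero of {n_total} interaction rows survive filtering "
            f"(organism={organism_id}, require_evidence={require_evidence})"
        )
    logger.info(
        "CTD conversion kept %d of %d interaction rows", len(df), n_total
    )

    sigs: list[Signature] = []
    grouped = df.groupby(resolved["chemical_id"], sort=True)
    for chem_id, rows in grouped:
        genes = frozenset(g.strip() for g in rows[resolved["gene_id"]] if g.strip())
        if not genes:
            continue
        name = rows[resolved["chemical_name"]].iloc[0].strip() or None
        sigs.append(Signature(compound_id=str(chem_id), genes=genes, compound_name=name))
    if not sigs:
        raise ValueError(f"{path}: no signatures after grouping")
    db = SignatureDB(signatures=tuple(sigs), source=f"CTD:{path.name}")
    logger.info(
        "built signature database: %d compounds over %d unique genes",
        db.n_compounds, db.n_genes,
    )
    return db


def restrict_to_instance(
    db: SignatureDB, instance: RankedInstance, min_overlap: int = 1
) -> SignatureDB:
    """Intersect every signature with the instance's genes and set ``t``.

    Signatures overlapping fewer than ``min_overlap`` instance genes are
    removed (counted in a logged summary).  Idempotent.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    kept: list[Signature] = []
    removed = 0
    for sig in db:
        overlap = frozenset(g for g in sig.genes if g in instance)
        if len(overlap) >= min_overlap:
            kept.append(replace(sig, genes=overlap, t=len(overlap)))
        else:
            removed += 1
    if removed:
        logger.info(
            "restriction removed %d of %d signatures with overlap < %d",
            removed, db.n_compounds, min_overlap,
        )
    if not kept:
        raise ValueError("no signature overlaps instance")
    return SignatureDB(signatures=tuple(kept), source=db.source)
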
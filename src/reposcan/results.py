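"""Result table I/O: TSV output with a JSON metadata sidecar.

Every screen writes two files: the ranked compound table and a sidecar
(``<out>.meta.json``) recording the bootstrap count, seed, overlap
threshold, p-value rule and SHA-256 digests of the inputs — enough to
reconstruct the run exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ks_core import EnrichmentResult

__all__ = ["results_to_frame", "write_results", "read_results", "file_digest"]

_COLUMNS = ["compound_id", "compound_name", "t", "ks", "p_value", "fdr"]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Result rows as a DataFrame in screen output order."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "compound_name": [r.compound_name or "" for r in results],
            "t": [r.t for r in results],
            "ks": [r.ks for r in results],
            "p_value": [r.p for r in results],
            "fdr": [r.q for r in results],
        }
    )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_results(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Write the result TSV (floats at 6 significant digits) and its sidecar."""
    path = Path(path)
    frame = results_to_frame(results)
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.compound_id}\t{row.compound_name}\t{row.t}\t"
                f"{row.ks:.6g}\t{row.p_value:.6g}\t{row.fdr:.6g}\n"
            )
    if metadata is not None:
        sidecar = path.with_name(path.name + ".meta.json")
        with open(sidecar, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return path


def read_results(path: str | Path) -> list[EnrichmentResult]:
    """Read a result TSV back into EnrichmentResult rows (order preserved)."""
    frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str}, keep_default_na=False)
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    return [
        EnrichmentResult(
            compound_id=str(row.compound_id),
            compound_name=str(row.compound_name) or None,
            t=int(row.t),
            ks=float(row.ks),
            p=float(row.p_value),
            q=float(row.fdr),
        )
        for row in frame.itertuples(index=False)
    ]
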
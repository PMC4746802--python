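"""Shared fixtures: tiny instances and a hand-enumerable synthetic CTD dump."""

from __future__ import annotations

import pytest

from reposcan import RankedInstance

CTD_HEADER = [
    "ChemicalName", "ChemicalID", "CasRN", "GeneSymbol", "GeneID",
    "GeneForms", "Organism", "OrganismID", "Interaction",
    "InteractionActions", "PubMedIDs",
]


def _row(name, chem, symbol, gid, form, org, orgid, pmids):
    return [name, chem, "", symbol, str(gid), form, org, str(orgid),
            f"{name} interacts with {symbol}", "affects^binding", pmids]


# 50 interaction rows whose human/evidence-filtered grouping is known by hand
# (see CTD_EXPECTED_* below).  Mixed organisms, missing evidence, repeated
# chemical-gene pairs and gene-product forms are all represented.
CTD_ROWS = (
    # drugA: human genes 1, 2 with evidence; gene 1 again as protein form;
    # gene 3 lacks evidence; gene 1 in mouse
    [_row("drugA", "MESH:D000001", "A1BG", 1, "gene", "Homo sapiens", 9606, "100")]
    + [_row("drugA", "MESH:D000001", "A2M", 2, "mRNA", "Homo sapiens", 9606, "101|102")]
    + [_row("drugA", "MESH:D000001", "A1BG", 1, "protein", "Homo sapiens", 9606, "103")]
    + [_row("drugA", "MESH:D000001", "NAT1", 3, "gene", "Homo sapiens", 9606, "")]
    + [_row("drugA", "MESH:D000001", "A1bg", 117586, "gene", "Mus musculus", 10090, "104")]
    # drugB: human genes 2, 3, 4 with evidence (gene 2 twice)
    + [_row("drugB", "MESH:D000002", "A2M", 2, "gene", "Homo sapiens", 9606, "200")]
    + [_row("drugB", "MESH:D000002", "NAT1", 3, "protein", "Homo sapiens", 9606, "201")]
    + [_row("drugB", "MESH:D000002", "NAT2", 4, "gene", "Homo sapiens", 9606, "202")]
    + [_row("drugB", "MESH:D000002", "A2M", 2, "mRNA", "Homo sapiens", 9606, "203")]
    # drugC: mouse only -> excluded entirely
    + [_row("drugC", "MESH:D000003", "A1bg", 117586, "gene", "Mus musculus", 10090, "300")]
    # drugD: human but never evidence-supported
    + [_row("drugD", "MESH:D000004", "NAT2", 4, "gene", "Homo sapiens", 9606, "")]
    + [_row("drugD", "MESH:D000004", "SERPINA3", 12, "gene", "Homo sapiens", 9606, "")]
    # drugE..drugL: one evidence-supported human gene each (genes 20..27)
    + [
        _row(f"drug{c}", f"MESH:D00001{i}", f"GENE{20 + i}", 20 + i, "gene",
             "Homo sapiens", 9606, str(500 + i))
        for i, c in enumerate("EFGHIJKL")
    ]
    # drugM: five human genes, alternating evidence
    + [
        _row("drugM", "MESH:D000030", f"GENE{40 + i}", 40 + i, "mRNA",
             "Homo sapiens", 9606, "600" if i % 2 == 0 else "")
        for i in range(5)
    ]
    # drugN: rat rows (excluded) plus two evidenced human genes
    + [_row("drugN", "MESH:D000031", "Nat2", 24421, "gene",
            "Rattus norvegicus", 10116, "700")]
    + [_row("drugN", "MESH:D000031", "GENE50", 50, "gene", "Homo sapiens", 9606, "701")]
    + [_row("drugN", "MESH:D000031", "GENE51", 51, "protein", "Homo sapiens", 9606, "702")]
    # filler compounds drugP..drugZ style: 2 evidenced human rows each
    + [
        _row(f"filler{i}", f"MESH:D0001{i:02d}", f"GENE{60 + 2 * i + j}",
             60 + 2 * i + j, "gene", "Homo sapiens", 9606, str(800 + i))
        for i in range(11)
        for j in range(2)
    ]
)
assert len(CTD_ROWS) == 50

# hand enumeration of the default conversion (organism 9606, evidence required)
CTD_EXPECTED_DEFAULT = {
    "MESH:D000001": {"1", "2"},
    "MESH:D000002": {"2", "3", "4"},
    **{f"MESH:D00001{i}": {str(20 + i)} for i in range(8)},
    "MESH:D000030": {"40", "42", "44"},
    "MESH:D000031": {"50", "51"},
    **{f"MESH:D0001{i:02d}": {str(60 + 2 * i), str(60 + 2 * i + 1)}
       for i in range(11)},
}

# hand enumeration with require_evidence=False (still human only)
CTD_EXPECTED_NO_EVIDENCE = {
    **CTD_EXPECTED_DEFAULT,
    "MESH:D000001": {"1", "2", "3"},
    "MESH:D000004": {"4", "12"},
    "MESH:D000030": {"40", "41", "42", "43", "44"},
}


def write_ctd(path, rows=CTD_ROWS, commented_header=False, header=CTD_HEADER):
    """Write a CTD-style dump; optionally with the header inside a # block."""
    with open(path, "w") as fh:
        if commented_header:
            fh.write("# Synthetic chemical-gene interactions fixture\n")
            fh.write("# Fields:\n")
            fh.write("# " + "\t".join(header) + "\n")
        else:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


@pytest.fixture
def ctd_file(tmp_path):
    return write_ctd(tmp_path / "ctd_ixns.tsv")


@pytest.fixture
def instance10():
    """Ten genes g1..g10 in rank order, no scores."""
    return RankedInstance(genes=tuple(f"g{i}" for i in range(1, 11)))
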
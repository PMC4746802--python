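"""Convert a raw chemical-gene interaction dump into a signature database.

Writes a miniature CTD-style dump (the public `chem_gene_ixns` layout),
converts it keeping only literature-supported human interactions, and
round-trips the result through GMT.
"""

import tempfile
from pathlib import Path

from reposcan import convert_ctd, read_gmt, write_gmt

HEADER = ("ChemicalName\tChemicalID\tCasRN\tGeneSymbol\tGeneID\tGeneForms\t"
          "Organism\tOrganismID\tInteraction\tInteractionActions\tPubMedIDs")
ROWS = [
    # name, chem, cas, symbol, gene, form, organism, taxon, interaction, actions, pmids
    "aspirin\tMESH:D001241\t\tPTGS2\t5743\tgene\tHomo sapiens\t9606\tx\taffects\t100",
    "aspirin\tMESH:D001241\t\tIL6\t3569\tmRNA\tHomo sapiens\t9606\tx\taffects\t101",
    "aspirin\tMESH:D001241\t\tPtgs2\t19225\tgene\tMus musculus\t10090\tx\taffects\t102",
    "caffeine\tMESH:D002110\t\tADORA2A\t135\tgene\tHomo sapiens\t9606\tx\taffects\t103",
    "caffeine\tMESH:D002110\t\tCYP1A2\t1544\tprotein\tHomo sapiens\t9606\tx\taffects\t",
]

with tempfile.TemporaryDirectory() as tmp:
    dump = Path(tmp) / "chem_gene_ixns.tsv"
    dump.write_text(HEADER + "\n" + "\n".join(ROWS) + "\n")

    db = convert_ctd(dump, organism_id="9606", require_evidence=True)
    print(f"kept {db.n_compounds} compounds over {db.n_genes} genes:")
    for sig in db:
        print(f"  {sig.compound_id} ({sig.compound_name}): {sorted(sig.genes)}")

    gmt = Path(tmp) / "signatures.gmt"
    write_gmt(db, gmt)
    assert {s.compound_id: s.genes for s in read_gmt(gmt)} == {
        s.compound_id: s.genes for s in db
    }
    print("\nGMT round-trip preserves the compound -> gene-set mapping.")
    print("Note: the mouse row and the evidence-free caffeine row were dropped.")
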
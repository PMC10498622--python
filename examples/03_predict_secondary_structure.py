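"""Predict per-residue secondary structure for a peptide with non-natural
residues.

The query's non-natural residues (Iva, meT, Aib) are first mapped to
natural analogs, then matched without gaps against a reference set of
annotated peptide conformations; every window scoring >= 0.65 votes its
annotation onto the covered positions, and unmatched positions stay '-'.

The bundled reference set is synthetic (random sequences with run-shaped
annotations), so this example also adds one annotated homolog of the
query — the situation a curated database of bioactive conformations
provides for real peptides.
"""

from pepkit import build_sequence, load_default_library, predict_secstruct
from pepkit.fixtures import FixtureSpec, make_reference_db, reference_db_to_tsv
from pepkit.secstruct import ReferenceEntry, load_reference_db, natural_query

library = load_default_library()
db = load_reference_db(reference_db_to_tsv(make_reference_db(FixtureSpec())))

seq = build_sequence("N-Iva-F-D-I-meT-N-A-L-W-Y-Aib-K", library)
mapped = natural_query(seq)
print("query (BILN)    : N-Iva-F-D-I-meT-N-A-L-W-Y-Aib-K")
print("natural analogs :", mapped)

print("against random reference only :",
      predict_secstruct(seq, db, threshold=0.65))
# All '-': no random entry is similar enough, so no window votes.

# a single-residue variant of the mapped query, annotated mostly helical
db.entries.append(ReferenceEntry("NAFDLTNALWYAK", "-HHHHHHHHHHH-"))
print("with one annotated homolog    :",
      predict_secstruct(seq, db, threshold=0.65))
# The homolog's windows now cover the query and vote the helix through;
# the modified residues inherit the context of their natural analogs.
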
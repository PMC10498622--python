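import pytest

from pepkit.fixtures import (
    FixtureSpec,
    make_monomer_sdf,
    make_reference_db,
    reference_db_to_tsv,
)
from pepkit.monomers import ingest_monomer_sdf
from pepkit.secstruct import default_matrix, load_reference_db

#: the six notation examples exercised throughout the suite:
#: (BILN, HELM, FASTA-or-None)
NOTATION_EXAMPLES = [
    ("P-E-P-T-I-D-E", "PEPTIDE1{P.E.P.T.I.D.E}$$$$V2.0", "PEPTIDE"),
    ("ac-D-T-H-F-E-I-A-am", "PEPTIDE1{[ac].D.T.H.F.E.I.A.[am]}$$$$V2.0",
     None),
    ("C(1,3)-A-A-A-C(1,3)",
     "PEPTIDE1{C.A.A.A.C} $PEPTIDE1,PEPTIDE1,1:R3-5:R3$$$V2.0", "CAAAC"),
    ("C(1,1)-A-A-A-C(1,2)",
     "PEPTIDE1{C.A.A.A.C} $PEPTIDE1,PEPTIDE1,1:R1-5:R2$$$V2.0", "CAAAC"),
    ("A-G-Q-A-A-K(1,3)-E-F-I-A-A.G-L-E-E(1,3)",
     "PEPTIDE1{A.G.Q.A.A.K.E.F.I.A.A}| PEPTIDE2{G.L.E.E} "
     "$PEPTIDE1,PEPTIDE2,6:R3-4:R3$$$V2.0", None),
    ("N-Iva-F-D-I-meT-N-A-L-W-Y-Aib-K",
     "PEPTIDE1{N.[Iva].F.D.I.[meT].N.A.L.W.Y.[Aib].K} $$$$V2.0", None),
]

OXYTOCIN_BILN = "C(1,3)-Y-I-Q-N-C(1,3)-P-L-G"


@pytest.fixture(scope="session")
def library():
    return ingest_monomer_sdf(make_monomer_sdf(FixtureSpec()))


@pytest.fixture(scope="session")
def reference_db():
    return load_reference_db(
        reference_db_to_tsv(make_reference_db(FixtureSpec()))
    )


@pytest.fixture(scope="session")
def blosum62():
    return default_matrix()
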
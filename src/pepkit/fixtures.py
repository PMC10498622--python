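"""Self-contained test inputs: a minimal monomer SDF and a synthetic
secondary-structure reference set.

Everything the package needs to run — a monomer dictionary covering the 20
proteinogenic amino acids, acetyl/amide caps and a few non-natural residues,
plus a reference database of (sequence, secondary-structure) pairs — is
generated programmatically here, so no external download or deposited
accession is ever required.

The monomer structures are written as SMILES with numbered dummy atoms
(``[*:1]``, ``[*:2]``, ``[*:3]``) marking the R-group attachment points:
R1 is the backbone amine, R2 the backbone carboxyl and R3 a side-chain
attachment.  The leaving group recorded for each R-group (H for amines and
thiols, OH for carboxyls) is what replaces the dummy atom when the R-group
does not form an inter-monomer bond.

The synthetic reference database emulates a collection of short bioactive
peptide conformations: random sequences over the 20 standard letters whose
annotation strings are built from helix runs (>= 5 residues), strand runs
(>= 3 residues) and coil filler at configurable proportions.  It reproduces
the composition of a curated structural database, not its sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "FixtureSpec",
    "make_monomer_sdf",
    "make_reference_db",
    "reference_db_to_tsv",
    "reference_db_to_fasta",
    "NATURAL_MONOMERS",
    "CAP_MONOMERS",
    "NNAA_MONOMERS",
]

# symbol -> (name, smiles-with-R-group-dummies, leaving groups, pdb code)
NATURAL_MONOMERS = {
    "A": ("Alanine", "[*:1]N[C@@H](C)C(=O)[*:2]", {1: "H", 2: "OH"}, "ALA"),
    "R": ("Arginine", "[*:1]N[C@@H](CCCNC(=N)N)C(=O)[*:2]", {1: "H", 2: "OH"}, "ARG"),
    "N": ("Asparagine", "[*:1]N[C@@H](CC(N)=O)C(=O)[*:2]", {1: "H", 2: "OH"}, "ASN"),
    "D": ("Aspartic acid", "[*:1]N[C@@H](CC(=O)[*:3])C(=O)[*:2]",
          {1: "H", 2: "OH", 3: "OH"}, "ASP"),
    "C": ("Cysteine", "[*:1]N[C@@H](CS[*:3])C(=O)[*:2]",
          {1: "H", 2: "OH", 3: "H"}, "CYS"),
    "E": ("Glutamic acid", "[*:1]N[C@@H](CCC(=O)[*:3])C(=O)[*:2]",
          {1: "H", 2: "OH", 3: "OH"}, "GLU"),
    "Q": ("Glutamine", "[*:1]N[C@@H](CCC(N)=O)C(=O)[*:2]", {1: "H", 2: "OH"}, "GLN"),
    "G": ("Glycine", "[*:1]NCC(=O)[*:2]", {1: "H", 2: "OH"}, "GLY"),
    "H": ("Histidine", "[*:1]N[C@@H](Cc1c[nH]cn1)C(=O)[*:2]", {1: "H", 2: "OH"}, "HIS"),
    "I": ("Isoleucine", "[*:1]N[C@@H]([C@@H](C)CC)C(=O)[*:2]", {1: "H", 2: "OH"}, "ILE"),
    "L": ("Leucine", "[*:1]N[C@@H](CC(C)C)C(=O)[*:2]", {1: "H", 2: "OH"}, "LEU"),
    "K": ("Lysine", "[*:1]N[C@@H](CCCCN[*:3])C(=O)[*:2]",
          {1: "H", 2: "OH", 3: "H"}, "LYS"),
    "M": ("Methionine", "[*:1]N[C@@H](CCSC)C(=O)[*:2]", {1: "H", 2: "OH"}, "MET"),
    "F": ("Phenylalanine", "[*:1]N[C@@H](Cc1ccccc1)C(=O)[*:2]", {1: "H", 2: "OH"}, "PHE"),
    "P": ("Proline", "[*:1]N1CCC[C@H]1C(=O)[*:2]", {1: "H", 2: "OH"}, "PRO"),
    "S": ("Serine", "[*:1]N[C@@H](CO[*:3])C(=O)[*:2]",
          {1: "H", 2: "OH", 3: "H"}, "SER"),
    "T": ("Threonine", "[*:1]N[C@@H]([C@H](O)C)C(=O)[*:2]", {1: "H", 2: "OH"}, "THR"),
    "W": ("Tryptophan", "[*:1]N[C@@H](Cc1c[nH]c2ccccc12)C(=O)[*:2]",
          {1: "H", 2: "OH"}, "TRP"),
    "Y": ("Tyrosine", "[*:1]N[C@@H](Cc1ccc(O)cc1)C(=O)[*:2]", {1: "H", 2: "OH"}, "TYR"),
    "V": ("Valine", "[*:1]N[C@@H](C(C)C)C(=O)[*:2]", {1: "H", 2: "OH"}, "VAL"),
}

# caps expose a single R-group: ac bonds through its carbonyl (an R2-style
# connector), am through its nitrogen (R1-style)
CAP_MONOMERS = {
    "ac": ("Acetyl", "CC(=O)[*:2]", {2: "OH"}, "ACE"),
    "am": ("C-terminal amide", "[*:1]N", {1: "H"}, "NH2"),
}

# non-natural amino acids with their natural-analog annotations
NNAA_MONOMERS = {
    "Aib": ("Alpha-aminoisobutyric acid", "[*:1]NC(C)(C)C(=O)[*:2]",
            {1: "H", 2: "OH"}, "AIB", "A"),
    "Iva": ("Isovaline", "[*:1]N[C@](C)(CC)C(=O)[*:2]",
            {1: "H", 2: "OH"}, None, "A"),
    "meT": ("N-Methyl-Threonine", "[*:1]N(C)[C@@H]([C@H](O)C)C(=O)[*:2]",
            {1: "H", 2: "OH"}, None, "T"),
}


@dataclass
class FixtureSpec:
    """Parameters of the generated fixtures.

    ``proportions`` follow the composition reported for curated sets of
    short bioactive peptides: roughly 30% helical content, 10% strand,
    the rest coil/turn.
    """

    include_naturals: bool = True
    include_caps: bool = True
    include_nnaa: bool = True
    db_size: int = 50
    proportions: dict = field(
        default_factory=lambda: {"H": 0.30, "E": 0.10, "-": 0.60}
    )
    length_range: tuple = (5, 30)
    seed: int = 2023

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {total}")
        lo, hi = self.length_range
        if not (5 <= lo <= hi <= 30):
            raise ValueError("length_range must lie within [5, 30]")


def _monomer_records(spec: FixtureSpec):
    if spec.include_naturals:
        for sym, (name, smi, leaving, pdb) in NATURAL_MONOMERS.items():
            yield name, "amino acid", sym, smi, leaving, pdb, None
    if spec.include_caps:
        for sym, (name, smi, leaving, pdb) in CAP_MONOMERS.items():
            yield name, "cap", sym, smi, leaving, pdb, None
    if spec.include_nnaa:
        for sym, (name, smi, leaving, pdb, analog) in NNAA_MONOMERS.items():
            yield name, "amino acid", sym, smi, leaving, pdb, analog


def make_monomer_sdf(spec: FixtureSpec | None = None) -> str:
    """Emit the monomer dictionary as an SDF text block.

    Each record carries the tags consumed by
    :func:`pepkit.monomers.ingest_monomer_sdf`: ``name``, ``monomerType``,
    ``symbol``, ``leavingGroups`` (``"1:H;2:OH"`` style), optional
    ``naturalAnalog`` and optional ``pdbName``.  R-group attachment points
    are dummy atoms whose atom-map number is the R-group index; the mapping
    survives the V2000 round trip in the atom block's mapping column.
    """
    spec = spec or FixtureSpec()
    out = io.StringIO()
    for name, role, sym, smi, leaving, pdb, analog in _monomer_records(spec):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - definitions are static
            raise ValueError(f"bad fixture SMILES for {sym}: {smi}")
        mol.SetProp("_Name", sym)
        block = Chem.MolToMolBlock(mol)
        out.write(block)
        out.write(f">  <name>\n{name}\n\n")
        out.write(f">  <monomerType>\n{role}\n\n")
        out.write(f">  <symbol>\n{sym}\n\n")
        lg = ";".join(f"{idx}:{frag}" for idx, frag in sorted(leaving.items()))
        out.write(f">  <leavingGroups>\n{lg}\n\n")
        if analog:
            out.write(f">  <naturalAnalog>\n{analog}\n\n")
        if pdb:
            out.write(f">  <pdbName>\n{pdb}\n\n")
        out.write(f">  <smiles>\n{smi}\n\n")
        out.write("$$$$\n")
    return out.getvalue()


_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def _ss_string(length: int, proportions: dict, rng: np.random.Generator) -> str:
    """Build an annotation string from category runs.

    Helix runs are at least 5 residues, strand runs at least 3; coil fills
    with short runs.  Categories are drawn at the requested proportions.
    """
    cats = sorted(proportions)
    probs = np.array([proportions[c] for c in cats])
    probs = probs / probs.sum()
    min_run = {"H": 5, "E": 3, "G": 3, "T": 2, "S": 2, "B": 1, "-": 1}
    parts: list[str] = []
    remaining = length
    while remaining > 0:
        cat = str(rng.choice(list(cats), p=probs))
        lo = min_run.get(cat, 1)
        if lo > remaining:
            cat, lo = "-", 1
        run = int(rng.integers(lo, min(remaining, lo + 4) + 1))
        parts.append(cat * run)
        remaining -= run
    return "".join(parts)[:length]


def make_reference_db(spec: FixtureSpec | None = None) -> list[tuple[str, str]]:
    """Generate ``db_size`` (sequence, ss) records, deterministic in the seed."""
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    seen = set()
    records: list[tuple[str, str]] = []
    lo, hi = spec.length_range
    while len(records) < spec.db_size:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(_LETTERS), size=length))
        if seq in seen:
            continue
        seen.add(seq)
        records.append((seq, _ss_string(length, spec.proportions, rng)))
    return records


def reference_db_to_tsv(records: list[tuple[str, str]]) -> str:
    return "".join(f"{seq}\t{ss}\n" for seq, ss in records)


def reference_db_to_fasta(records: list[tuple[str, str]]) -> str:
    out = []
    for i, (seq, ss) in enumerate(records):
        out.append(f">entry{i} ss={ss}\n{seq}\n")
    return "".join(out)
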
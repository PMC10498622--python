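"""Monomer dictionary: ingestion, validation and queries.

A monomer is a peptide building block — an amino acid or a capping group —
described by a molecular structure whose attachment points are dummy atoms
numbered R1 (backbone amine), R2 (backbone carboxyl) and R3+ (side chain).
Each R-group records the fragment (its *leaving group*, e.g. H at an amine,
OH at a carboxyl) that is removed when the R-group forms an inter-monomer
bond, or retained when it does not.

The on-disk format is an SDF stream in the style of public HELM monomer
collections: one V2000 record per monomer with data tags for the name, the
monomer type, the line-notation symbol, the leaving groups and, where
applicable, the natural analog.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field, replace

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .errors import (
    DuplicateSymbolError,
    MonomerError,
    MonomerIngestError,
    MonomerNotFoundError,
)

__all__ = [
    "RGroup",
    "Monomer",
    "MonomerLibrary",
    "ingest_monomer_sdf",
    "write_monomer_sdf",
    "get_monomer",
    "assign_natural_analog",
    "assign_pdb_code",
    "validate_monomer",
    "load_default_library",
]

STANDARD_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: chemical-component-dictionary codes for the residues shipped with the
#: default fixture library; anything else gets a generated code
CCD_CODES = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "ac": "ACE", "am": "NH2", "Aib": "AIB",
}

_MANDATORY_TAGS = ("name", "monomerType", "symbol", "leavingGroups")
_ROLES = {"amino acid": "amino_acid", "amino_acid": "amino_acid", "cap": "cap"}


@dataclass(frozen=True)
class RGroup:
    """A numbered attachment point on a monomer.

    ``attachment_atom`` indexes the heavy atom that will carry the new bond;
    ``dummy_atom`` indexes the placeholder atom standing where either the
    bond partner or the leaving group will go.
    """

    index: int
    attachment_atom: int
    dummy_atom: int
    leaving_group: str  # "H", "OH", or "" for none


@dataclass
class Monomer:
    name: str
    symbol: str
    role: str  # "amino_acid" | "cap"
    structure: Chem.Mol  # with R-group dummy atoms (atom map = R index)
    r_groups: dict[int, RGroup]
    natural_analog: str | None = None
    pdb_code: str | None = None
    smiles: str | None = None

    def has_rgroup(self, index: int) -> bool:
        return index in self.r_groups


@dataclass
class MonomerLibrary:
    """Symbol-indexed monomer dictionary."""

    entries: dict[str, Monomer] = field(default_factory=dict)
    known_pdb_codes: set[str] = field(default_factory=set)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, symbol: str) -> Monomer:
        return get_monomer(self, symbol)

    def symbols(self) -> list[str]:
        return list(self.entries)


def _extract_rgroups(mol: Chem.Mol, leaving: dict[int, str]) -> dict[int, RGroup]:
    groups: dict[int, RGroup] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() > 0:
            idx = atom.GetAtomMapNum()
            nbrs = atom.GetNeighbors()
            if len(nbrs) != 1:
                raise MonomerIngestError(
                    f"R{idx} placeholder must have exactly one neighbor"
                )
            groups[idx] = RGroup(
                index=idx,
                attachment_atom=nbrs[0].GetIdx(),
                dummy_atom=atom.GetIdx(),
                leaving_group=leaving.get(idx, ""),
            )
    return groups


def _parse_leaving(tag: str) -> dict[int, str]:
    out: dict[int, str] = {}
    for part in tag.split(";"):
        part = part.strip()
        if not part:
            continue
        idx, _, frag = part.partition(":")
        out[int(idx)] = frag.strip()
    return out


def ingest_monomer_sdf(source) -> MonomerLibrary:
    """Build a :class:`MonomerLibrary` from an SDF stream.

    ``source`` may be SDF text, a path, or a file-like object.  Records with
    missing mandatory tags or unparsable structure blocks abort ingestion
    with an error naming the record; a duplicate symbol names both records.
    """
    text = _read_source(source)
    lib = MonomerLibrary()
    first_record: dict[str, int] = {}
    supplier = Chem.ForwardSDMolSupplier(io.BytesIO(text.encode()), sanitize=True,
                                         removeHs=False)
    RDLogger.DisableLog("rdApp.warning")
    try:
        for i, mol in enumerate(supplier):
            if mol is None:
                raise MonomerIngestError(f"record {i}: unparsable structure block")
            props = mol.GetPropsAsDict()
            missing = [t for t in _MANDATORY_TAGS if t not in props]
            if missing:
                label = props.get("symbol", props.get("name", f"record {i}"))
                raise MonomerIngestError(
                    f"record {i} ({label}): missing mandatory tag(s) "
                    + ", ".join(missing)
                )
            symbol = str(props["symbol"]).strip()
            if "-" in symbol or "." in symbol or not symbol:
                raise MonomerIngestError(
                    f"record {i}: symbol {symbol!r} is empty or contains a "
                    "notation separator"
                )
            if symbol in lib.entries:
                raise DuplicateSymbolError(symbol, first_record[symbol], i)
            role = _ROLES.get(str(props["monomerType"]).strip().lower())
            if role is None:
                raise MonomerIngestError(
                    f"record {i} ({symbol}): unknown monomerType "
                    f"{props['monomerType']!r}"
                )
            leaving = _parse_leaving(str(props["leavingGroups"]))
            r_groups = _extract_rgroups(mol, leaving)
            monomer = Monomer(
                name=str(props["name"]).strip(),
                symbol=symbol,
                role=role,
                structure=mol,
                r_groups=r_groups,
                natural_analog=(str(props["naturalAnalog"]).strip()
                                if "naturalAnalog" in props else None),
                pdb_code=(str(props["pdbName"]).strip()
                          if "pdbName" in props else None),
                smiles=(str(props["smiles"]).strip()
                        if "smiles" in props else Chem.MolToSmiles(mol)),
            )
            violations = validate_monomer(monomer)
            if violations:
                raise MonomerIngestError(
                    f"record {i} ({symbol}): " + "; ".join(violations)
                )
            first_record[symbol] = i
            lib.entries[symbol] = monomer
            if monomer.pdb_code:
                lib.known_pdb_codes.add(monomer.pdb_code)
    finally:
        RDLogger.EnableLog("rdApp.warning")
    return lib


def write_monomer_sdf(library: MonomerLibrary) -> str:
    """Serialize a library back to the SDF dialect read by ingestion."""
    out = io.StringIO()
    role_names = {"amino_acid": "amino acid", "cap": "cap"}
    for symbol, m in library.entries.items():
        mol = Chem.Mol(m.structure)
        mol.SetProp("_Name", symbol)
        out.write(Chem.MolToMolBlock(mol))
        out.write(f">  <name>\n{m.name}\n\n")
        out.write(f">  <monomerType>\n{role_names[m.role]}\n\n")
        out.write(f">  <symbol>\n{symbol}\n\n")
        lg = ";".join(f"{i}:{g.leaving_group}" for i, g in sorted(m.r_groups.items()))
        out.write(f">  <leavingGroups>\n{lg}\n\n")
        if m.natural_analog:
            out.write(f">  <naturalAnalog>\n{m.natural_analog}\n\n")
        if m.pdb_code:
            out.write(f">  <pdbName>\n{m.pdb_code}\n\n")
        if m.smiles:
            out.write(f">  <smiles>\n{m.smiles}\n\n")
        out.write("$$$$\n")
    return out.getvalue()


def get_monomer(library: MonomerLibrary, symbol: str) -> Monomer:
    try:
        return library.entries[symbol]
    except KeyError:
        raise MonomerNotFoundError(symbol) from None


def _fingerprint_mol(monomer: Monomer) -> Chem.Mol:
    """Strip R-group placeholders (replace with H) before fingerprinting."""
    rw = Chem.RWMol(monomer.structure)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.RemoveHs(mol)


_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def assign_natural_analog(monomer: Monomer, library: MonomerLibrary) -> str:
    """Map a monomer to its closest standard one-letter residue.

    An explicit ``natural_analog`` annotation wins.  Otherwise a circular
    fingerprint (radius 2, 2048 bits) Tanimoto comparison against the 20
    standard residues is run; the best hit is returned when its score is at
    least 0.5, alanine otherwise.  Ties resolve to the alphabetically first
    letter, so the assignment is deterministic.
    """
    if monomer.natural_analog:
        return monomer.natural_analog
    if monomer.structure is None or monomer.structure.GetNumAtoms() == 0:
        raise MonomerError(f"monomer {monomer.symbol!r} has an empty structure")
    query_fp = _FPGEN.GetFingerprint(_fingerprint_mol(monomer))
    best_letter, best_score = "A", -1.0
    for letter in sorted(STANDARD_LETTERS):
        if letter not in library:
            raise MonomerError(
                f"library lacks standard residue {letter!r} needed for "
                "analog assignment"
            )
        ref_fp = _FPGEN.GetFingerprint(_fingerprint_mol(library[letter]))
        score = DataStructs.TanimotoSimilarity(query_fp, ref_fp)
        if score > best_score + 1e-12:
            best_letter, best_score = letter, score
    return best_letter if best_score >= 0.5 else "A"


_CODE_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def assign_pdb_code(
    monomer: Monomer,
    known_codes: set[str],
    code_table: dict[str, str] | None = None,
) -> str:
    """Return a unique 3-character residue code for the monomer.

    Monomers present in the chemical component dictionary keep their
    standard code (``code_table`` maps symbol or name to code and defaults
    to the codes bundled for the fixture residues).  Anything else receives
    a code derived deterministically from the monomer name — a hash over
    the [A-Z0-9]^3 code space with linear probing against ``known_codes``
    — so repeated runs allocate identical codes.
    """
    table = CCD_CODES if code_table is None else code_table
    code = monomer.pdb_code or table.get(monomer.symbol) or table.get(monomer.name)
    if code:
        return code
    if len(known_codes) >= 36 ** 3:
        raise MonomerError("PDB code space exhausted")
    digest = hashlib.sha256(monomer.name.encode()).digest()
    start = int.from_bytes(digest[:8], "big") % 36 ** 3
    for probe in range(36 ** 3):
        value = (start + probe) % 36 ** 3
        code = "".join(
            _CODE_ALPHABET[(value // 36 ** k) % 36] for k in (2, 1, 0)
        )
        if code not in known_codes:
            return code
    raise MonomerError("PDB code space exhausted")  # pragma: no cover


def validate_monomer(monomer: Monomer) -> list[str]:
    """Check the monomer invariants; return human-readable violations."""
    violations = []
    if not monomer.symbol:
        violations.append("symbol: must be non-empty")
    if monomer.role not in ("amino_acid", "cap"):
        violations.append(f"role: unknown role {monomer.role!r}")
    if monomer.structure is None or monomer.structure.GetNumAtoms() == 0:
        violations.append("structure: empty")
        return violations
    n_atoms = monomer.structure.GetNumAtoms()
    placeholder_maps = {
        a.GetAtomMapNum()
        for a in monomer.structure.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    }
    if placeholder_maps != set(monomer.r_groups):
        violations.append(
            "r_groups: placeholder atoms "
            f"{sorted(placeholder_maps)} do not match declared R-groups "
            f"{sorted(monomer.r_groups)}"
        )
    for idx, g in monomer.r_groups.items():
        if not (0 <= g.attachment_atom < n_atoms):
            violations.append(
                f"r_groups: R{idx} attachment atom {g.attachment_atom} "
                "does not exist in the structure"
            )
        if g.leaving_group not in ("", "H", "OH"):
            violations.append(
                f"r_groups: R{idx} leaving group {g.leaving_group!r} "
                "is not supported (H, OH or empty)"
            )
    if monomer.role == "cap" and len(monomer.r_groups) < 1:
        violations.append("r_groups: cap monomers must expose an R-group")
    return violations


_DEFAULT_LIBRARY: MonomerLibrary | None = None


def load_default_library() -> MonomerLibrary:
    """The built-in fixture library (20 naturals + ac/am + Aib/Iva/meT)."""
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        from .fixtures import FixtureSpec, make_monomer_sdf

        _DEFAULT_LIBRARY = ingest_monomer_sdf(make_monomer_sdf(FixtureSpec()))
    return _DEFAULT_LIBRARY


def _read_source(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, str) and "\n" not in source and source.endswith(".sdf"):
        with open(source) as fh:
            return fh.read()
    if isinstance(source, str):
        return source
    with open(source) as fh:  # pathlib.Path
        return fh.read()
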
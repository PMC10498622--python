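"""Restraint-guided 3D conformer generation and PDB export.

Secondary-structure categories are translated into extra entries of the
distance-geometry bounds matrix before embedding with the
experimental-torsion knowledge method (ETKDGv3) and force-field
minimization:

* a helix run (>= 5 residues of H, 3/10-helix G allowed inside an
  H-dominated run) pins the i/i+4 hydrogen-bond geometry:
  O(i)-N(i+4) in [2.7, 3.3] A and CA(i)-CA(i+4) in [5.8, 6.6] A;
* a strand run (>= 3 consecutive E) enforces intra-strand extension:
  CA(i)-CA(i+2) in [6.2, 7.2] A.

Injected restraints only ever tighten the default bounds.  Inter-strand
sheet pairing cannot be inferred from a category string and is not
restrained.  The values are ideal-geometry defaults collected in
:class:`RestraintConfig` for tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import DistanceGeometry as DG
from rdkit.Chem import ChemicalForceFields  # noqa: F401  (registers FF classes)
from rdkit.Chem import rdDistGeom, rdForceFieldHelpers, rdMolTransforms

from .errors import EmbeddingError, PepkitError, SSLengthError
from .molecule import MolecularGraph
from .naming import name_hydrogens
from .secstruct import SSAnnotation
from .sequence import Sequence

__all__ = [
    "RestraintConfig",
    "DistanceBounds",
    "Conformer3D",
    "build_distance_bounds",
    "embed_conformer",
    "write_pdb",
    "check_ss_geometry",
]


@dataclass(frozen=True)
class RestraintConfig:
    """Restraint distances (Angstrom), run-length minima and embedding knobs."""

    helix_min_run: int = 5
    helix_on_lower: float = 2.7
    helix_on_upper: float = 3.3
    helix_caca_lower: float = 5.8
    helix_caca_upper: float = 6.6
    strand_min_run: int = 3
    strand_caca_lower: float = 6.2
    strand_caca_upper: float = 7.2
    minimize_iters: int = 500
    force_field: str = "MMFF"  # "MMFF" | "UFF"
    #: force constant (kcal/mol/A^2) holding the restraint windows during
    #: minimization; strong enough that relaxation cannot unfold them
    restraint_force_constant: float = 500.0
    embed_retries: int = 3
    seed: int = 2023
    #: tolerance widening applied when checking realized distances
    check_lower_slack: float = 0.5
    check_upper_slack: float = 0.3


@dataclass
class DistanceBounds:
    """Extra atom-pair bounds injected into the embedding bounds matrix."""

    pairs: list[tuple[int, int, float, float]] = field(default_factory=list)

    def add(self, a: int, b: int, lower: float, upper: float) -> None:
        if a == b:
            raise PepkitError("distance bound requires two distinct atoms")
        if not (0 < lower <= upper):
            raise PepkitError(
                f"invalid bounds [{lower}, {upper}] for atoms {a}, {b}"
            )
        self.pairs.append((min(a, b), max(a, b), lower, upper))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Conformer3D:
    coords3d: np.ndarray  # (n_atoms, 3), Angstrom
    mol: Chem.Mol  # explicit-H molecule carrying the conformer
    atom_monomer: list[int]
    atom_names: list[str]
    provenance: dict = field(default_factory=dict)


def _runs(ss: str) -> list[tuple[int, int, str]]:
    """Maximal runs of helix ({H,G}, H-dominated) and strand (E) residues."""
    out = []
    i = 0
    n = len(ss)
    while i < n:
        if ss[i] in "HG":
            j = i
            while j < n and ss[j] in "HG":
                j += 1
            run = ss[i:j]
            if run.count("H") >= run.count("G"):
                out.append((i, j, "helix"))
            i = j
        elif ss[i] == "E":
            j = i
            while j < n and ss[j] == "E":
                j += 1
            out.append((i, j, "strand"))
            i = j
        else:
            i += 1
    return out


def build_distance_bounds(
    graph: MolecularGraph,
    seq: Sequence,
    ss: SSAnnotation | str,
    config: RestraintConfig | None = None,
) -> DistanceBounds:
    """Translate a category string into atom-pair distance bounds.

    ``ss`` has one category per amino-acid monomer (caps carry none).
    Atom indices refer to the heavy-atom graph; they are remapped when
    hydrogens are added for embedding.
    """
    config = config or RestraintConfig()
    ss = str(ss)
    residues = seq.amino_acid_indices()
    if len(ss) != len(residues):
        raise SSLengthError(len(residues), len(ss))

    def atom(res_pos: int, name: str) -> int | None:
        try:
            return graph.atom_index(residues[res_pos], name)
        except KeyError:
            return None

    bounds = DistanceBounds()
    for start, end, kind in _runs(ss):
        if kind == "helix" and end - start >= config.helix_min_run:
            for i in range(start, end - 4):
                o_i, n_i4 = atom(i, "O"), atom(i + 4, "N")
                ca_i, ca_i4 = atom(i, "CA"), atom(i + 4, "CA")
                if o_i is not None and n_i4 is not None:
                    bounds.add(o_i, n_i4,
                               config.helix_on_lower, config.helix_on_upper)
                if ca_i is not None and ca_i4 is not None:
                    bounds.add(ca_i, ca_i4,
                               config.helix_caca_lower, config.helix_caca_upper)
        elif kind == "strand" and end - start >= config.strand_min_run:
            for i in range(start, end - 2):
                ca_i, ca_i2 = atom(i, "CA"), atom(i + 2, "CA")
                if ca_i is not None and ca_i2 is not None:
                    bounds.add(ca_i, ca_i2,
                               config.strand_caca_lower,
                               config.strand_caca_upper)
    return bounds


def _with_hydrogens(graph: MolecularGraph) -> tuple[Chem.Mol, list[int], list[str]]:
    """Explicit-H copy plus per-atom residue indices and names."""
    mol = Chem.AddHs(Chem.Mol(graph.mol))
    n_heavy = graph.num_atoms
    atom_monomer = list(graph.atom_monomer)
    heavy_names = {i: n for i, n in enumerate(graph.atom_names) if n}
    # hydrogens appended after the heavy atoms; inherit the parent residue
    for atom in mol.GetAtoms():
        if atom.GetIdx() >= n_heavy:
            parent = atom.GetNeighbors()[0].GetIdx()
            atom_monomer.append(atom_monomer[parent])
    n_term = {
        i for i, name in heavy_names.items()
        if name == "N" and sum(
            1 for nb in mol.GetAtomWithIdx(i).GetNeighbors()
            if nb.GetAtomicNum() == 1
        ) >= 2
    }
    h_names = name_hydrogens(mol, heavy_names, n_terminal_n=n_term)
    names = []
    for i in range(mol.GetNumAtoms()):
        if i in heavy_names:
            names.append(heavy_names[i])
        elif i in h_names:
            names.append(h_names[i])
        else:
            names.append(f"X{i}")
    return mol, atom_monomer, names


def embed_conformer(
    graph: MolecularGraph,
    bounds: DistanceBounds | None = None,
    seed: int | None = None,
    config: RestraintConfig | None = None,
) -> Conformer3D:
    """Embed a 3D conformer under the injected bounds and minimize it.

    The same graph, bounds and seed reproduce identical coordinates.
    Injection only tightens the engine's default bounds; an infeasible
    pair (tightened lower above the tightened upper) is an error.
    """
    config = config or RestraintConfig()
    seed = config.seed if seed is None else seed
    bounds = bounds or DistanceBounds()

    mol, atom_monomer, names = _with_hydrogens(graph)
    bm = rdDistGeom.GetMoleculeBoundsMatrix(mol)
    for a, b, lower, upper in bounds.pairs:
        lo = max(bm[b][a], lower)  # lower triangle holds lower bounds
        up = min(bm[a][b], upper)
        if lo > up + 1e-9:
            raise PepkitError(
                f"restraint [{lower}, {upper}] on atoms {a}-{b} is "
                f"incompatible with default bounds "
                f"[{bm[b][a]:.2f}, {bm[a][b]:.2f}]"
            )
        bm[b][a], bm[a][b] = lo, up
    if not DG.DoTriangleSmoothing(bm):
        raise PepkitError("triangle smoothing failed on the bounds matrix")

    cid = -1
    used_seed = seed
    for attempt in range(config.embed_retries):
        params = rdDistGeom.ETKDGv3()
        used_seed = seed + attempt
        params.randomSeed = used_seed
        params.SetBoundsMat(bm)
        # random initial coordinates embed large peptides far more
        # reliably than the default eigenvalue start
        params.useRandomCoords = attempt > 0 or mol.GetNumAtoms() > 200
        cid = rdDistGeom.EmbedMolecule(mol, params)
        if cid >= 0:
            break
    if cid < 0:
        raise EmbeddingError(
            f"embedding failed after {config.embed_retries} attempts "
            f"(seeds {seed}..{used_seed}); {mol.GetNumAtoms()} atoms, "
            f"{len(bounds)} extra bounds"
        )

    status = _minimize(mol, config, bounds)
    coords = mol.GetConformer().GetPositions().copy()
    return Conformer3D(
        coords3d=coords,
        mol=mol,
        atom_monomer=atom_monomer,
        atom_names=names,
        provenance={
            "seed": used_seed,
            "n_restraints": len(bounds),
            "minimization": status,
            "force_field": config.force_field,
        },
    )


def _minimize(mol: Chem.Mol, config: RestraintConfig,
              bounds: DistanceBounds) -> str:
    """Force-field minimization with the injected bounds kept as
    flat-bottomed harmonic distance constraints, so relaxing the geometry
    does not undo the secondary-structure restraints."""
    try:
        ff = None
        label = "UFF"
        if config.force_field.upper() == "MMFF" and \
                rdForceFieldHelpers.MMFFHasAllMoleculeParams(mol):
            props = rdForceFieldHelpers.MMFFGetMoleculeProperties(mol)
            ff = rdForceFieldHelpers.MMFFGetMoleculeForceField(mol, props)
            label = "MMFF"
        else:
            ff = rdForceFieldHelpers.UFFGetMoleculeForceField(mol)
        fc = config.restraint_force_constant
        for a, b, lower, upper in bounds.pairs:
            if label == "MMFF":
                ff.MMFFAddDistanceConstraint(a, b, False, lower, upper, fc)
            else:
                ff.UFFAddDistanceConstraint(a, b, False, lower, upper, fc)
        ff.Initialize()
        code = ff.Minimize(maxIts=config.minimize_iters)
        return f"{label}:{'converged' if code == 0 else 'maxiter'}"
    except Exception as exc:  # pragma: no cover - defensive
        return f"failed:{exc}"


# --- PDB export ------------------------------------------------------------

def write_pdb(
    conf: Conformer3D,
    graph: MolecularGraph,
    seq: Sequence,
) -> str:
    """Serialize the conformer as PDB text.

    One residue per monomer with its 3-letter code, chains lettered A, B,
    ... in notation order, IUPAC atom names, TER after each chain and
    CONECT records for the annotated (non-backbone) bonds such as
    disulfides.
    """
    from .monomers import assign_pdb_code

    n = len(seq.monomers)
    known: set[str] = set()
    code_of_symbol: dict[str, str] = {}
    res_codes: list[str] = []
    for monomer in seq.monomers:
        code = code_of_symbol.get(monomer.symbol)
        if code is None:
            code = assign_pdb_code(monomer, known)
            code_of_symbol[monomer.symbol] = code
            known.add(code)
        res_codes.append(code)

    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    # residue numbering restarts in every chain
    res_number: list[int] = []
    counters: dict[int, int] = {}
    for i in range(n):
        c = seq.chain_of[i]
        counters[c] = counters.get(c, 0) + 1
        res_number.append(counters[c])

    lines: list[str] = []
    serial_of: dict[int, int] = {}
    serial = 0
    standard = set(
        code for code in res_codes
        if code in {"ALA", "ARG", "ASN", "ASP", "CYS", "GLU", "GLN", "GLY",
                    "HIS", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER",
                    "THR", "TRP", "TYR", "VAL"}
    )
    order = sorted(
        range(len(conf.atom_monomer)),
        key=lambda a: (seq.chain_of[conf.atom_monomer[a]],
                       conf.atom_monomer[a], a),
    )
    prev_chain = None
    for a in order:
        mono = conf.atom_monomer[a]
        chain = seq.chain_of[mono]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        serial_of[a] = serial
        x, y, z = conf.coords3d[a]
        element = conf.mol.GetAtomWithIdx(a).GetSymbol().upper()
        name = conf.atom_names[a][:4]
        # column rule: names shorter than 4 start in column 14
        field_name = name if len(name) == 4 else f" {name:<3s}"
        record = "ATOM  " if res_codes[mono] in standard else "HETATM"
        lines.append(
            f"{record}{serial:5d} {field_name}{'':1s}{res_codes[mono]:>3s} "
            f"{chain_letters[chain % 26]}{res_number[mono]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{element:>2s}"
        )
    lines.append("TER")

    # CONECT for annotated bonds only (backbone connectivity is implied)
    for bond in seq.bonds:
        if bond.kind != "annotated":
            continue
        atoms = []
        for mono, rgroup in (bond.a, bond.b):
            g = seq.monomers[mono].r_groups[rgroup]
            att_name = graph.atom_names[
                _attachment_global(graph, seq, mono, rgroup)
            ]
            atoms.append(_conf_atom(conf, mono, att_name))
        a, b = atoms
        lines.append(f"CONECT{serial_of[a]:5d}{serial_of[b]:5d}")
        lines.append(f"CONECT{serial_of[b]:5d}{serial_of[a]:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _attachment_global(graph: MolecularGraph, seq: Sequence,
                       mono: int, rgroup: int) -> int:
    """Global heavy-atom index of an R-group's attachment atom."""
    local = seq.monomers[mono].r_groups[rgroup].attachment_atom
    name = seq.atom_names[mono].get(local)
    if name is None:
        raise PepkitError(
            f"attachment atom of R{rgroup} on monomer {mono} is unnamed"
        )
    return graph.atom_index(mono, name)


def _conf_atom(conf: Conformer3D, mono: int, name: str) -> int:
    for i, (m, n) in enumerate(zip(conf.atom_monomer, conf.atom_names)):
        if m == mono and n == name:
            return i
    raise KeyError(f"no atom named {name!r} in monomer {mono}")


# --- diagnostics -----------------------------------------------------------

@dataclass
class SSGeometryReport:
    """Realized restraint distances plus per-residue backbone dihedrals."""

    pairs: pd.DataFrame
    phi_psi: pd.DataFrame

    @property
    def satisfied_fraction(self) -> float:
        if len(self.pairs) == 0:
            return float("nan")
        return float(self.pairs["ok"].mean())


def check_ss_geometry(
    conf: Conformer3D,
    graph: MolecularGraph,
    seq: Sequence,
    ss: SSAnnotation | str,
    config: RestraintConfig | None = None,
) -> SSGeometryReport:
    """Report each restrained pair's realized distance (pass/fail against
    the slack-widened window) and the backbone phi/psi angles."""
    config = config or RestraintConfig()
    bounds = build_distance_bounds(graph, seq, ss, config)
    rows = []
    for a, b, lower, upper in bounds.pairs:
        d = float(np.linalg.norm(conf.coords3d[a] - conf.coords3d[b]))
        lo = lower - config.check_lower_slack
        up = upper + config.check_upper_slack
        rows.append({
            "atom_a": a, "atom_b": b,
            "name_a": conf.atom_names[a], "name_b": conf.atom_names[b],
            "lower": lower, "upper": upper, "distance": d,
            "ok": bool(lo <= d <= up),
        })
    pairs = pd.DataFrame(
        rows, columns=["atom_a", "atom_b", "name_a", "name_b",
                       "lower", "upper", "distance", "ok"]
    )

    residues = seq.amino_acid_indices()
    mol_conf = conf.mol.GetConformer()

    def catom(res: int, name: str) -> int | None:
        try:
            return _conf_atom(conf, residues[res], name)
        except KeyError:
            return None

    pp_rows = []
    for k, mono in enumerate(residues):
        n_i, ca_i, c_i = catom(k, "N"), catom(k, "CA"), catom(k, "C")
        phi = psi = float("nan")
        if k > 0 and None not in (n_i, ca_i, c_i):
            c_prev = catom(k - 1, "C")
            if c_prev is not None:
                phi = rdMolTransforms.GetDihedralDeg(
                    mol_conf, c_prev, n_i, ca_i, c_i)
        if k < len(residues) - 1 and None not in (n_i, ca_i, c_i):
            n_next = catom(k + 1, "N")
            if n_next is not None:
                psi = rdMolTransforms.GetDihedralDeg(
                    mol_conf, n_i, ca_i, c_i, n_next)
        pp_rows.append({"residue": k, "monomer": mono,
                        "symbol": seq.monomers[mono].symbol,
                        "phi": phi, "psi": psi})
    phi_psi = pd.DataFrame(
        pp_rows, columns=["residue", "monomer", "symbol", "phi", "psi"]
    )
    return SSGeometryReport(pairs=pairs, phi_psi=phi_psi)
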
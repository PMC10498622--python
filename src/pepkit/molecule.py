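"""Assemble a Sequence into one molecular graph and lay it out in 2D.

Assembly merges the monomer structures in global index order, then realizes
every bond of the Sequence by deleting the two R-group placeholder atoms
and joining the attachment atoms with a single bond.  R-groups that stay
unbonded keep their leaving group: an H placeholder simply disappears (the
implicit hydrogen returns on sanitization) and an OH placeholder becomes a
real oxygen — this is how the free C-terminus regains its carboxylic acid.

Two 2D layout modes are provided: the toolkit's standard depiction, and an
extended mode that pins the backbone to an ideal zig-zag and lets the
side chains settle around it, resolving residual clashes by reflecting
side chains about their CA-CB axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDepictor, rdMolDescriptors
from rdkit.Geometry import Point2D

from .errors import AssemblyError, PepkitError
from .sequence import Sequence, validate_sequence

__all__ = [
    "MolecularGraph",
    "assemble_molecule",
    "generate_2d_standard",
    "generate_2d_extended",
    "export_molecule",
    "molecular_formula",
    "min_pairwise_distance",
]


@dataclass
class MolecularGraph:
    """The assembled peptide: an RDKit molecule plus residue annotations."""

    mol: Chem.Mol
    atom_monomer: list[int]  # atom index -> monomer (residue) index
    atom_names: list[str | None]
    #: 2D layout mode used, if any ("standard" | "extended")
    layout: str | None = None

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def atoms_of_monomer(self, index: int) -> list[int]:
        return [i for i, m in enumerate(self.atom_monomer) if m == index]

    def atom_index(self, monomer: int, name: str) -> int:
        """Global atom index of the named atom in the given residue."""
        for i in self.atoms_of_monomer(monomer):
            if self.atom_names[i] == name:
                return i
        raise KeyError(f"no atom named {name!r} in monomer {monomer}")

    def coords2d(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        return np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
             for i in range(self.num_atoms)]
        )


def assemble_molecule(seq: Sequence) -> MolecularGraph:
    """Merge the Sequence's monomers into one sanitized molecule."""
    violations = validate_sequence(seq)
    if violations:
        raise AssemblyError(
            "sequence fails validation: " + "; ".join(violations)
        )
    if not seq.atom_names:
        raise AssemblyError("sequence has no atom names; run greekify first")

    combined = Chem.RWMol()
    offsets: list[int] = []
    for i, monomer in enumerate(seq.monomers):
        offsets.append(combined.GetNumAtoms())
        frag = Chem.Mol(monomer.structure)
        for atom in frag.GetAtoms():
            atom.SetIntProp("pk_mono", i)
            name = seq.atom_names[i].get(atom.GetIdx())
            if name is not None:
                atom.SetProp("pk_name", name)
        combined.InsertMol(frag)

    def slot_atoms(slot: tuple[int, int]) -> tuple[int, int]:
        mono, rgroup = slot
        g = seq.monomers[mono].r_groups[rgroup]
        return (offsets[mono] + g.dummy_atom, offsets[mono] + g.attachment_atom)

    to_remove: list[int] = []
    for bond in seq.bonds:
        dummy_a, att_a = slot_atoms(bond.a)
        dummy_b, att_b = slot_atoms(bond.b)
        to_remove.extend([dummy_a, dummy_b])
        combined.AddBond(att_a, att_b, Chem.BondType.SINGLE)

    for mono, rgroup in seq.cappings:
        g = seq.monomers[mono].r_groups[rgroup]
        dummy = offsets[mono] + g.dummy_atom
        if g.leaving_group == "OH":
            atom = combined.GetAtomWithIdx(dummy)
            atom.SetAtomicNum(8)
            atom.SetAtomMapNum(0)
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
            atom.SetNumRadicalElectrons(0)
            if not atom.HasProp("pk_name"):
                atom.SetProp("pk_name", "OXT")
        else:  # H or empty: drop the placeholder, implicit H returns
            to_remove.append(dummy)

    for idx in sorted(set(to_remove), reverse=True):
        combined.RemoveAtom(idx)

    mol = combined.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        culprit = _find_unsanitizable(seq)
        hint = f" (monomer {culprit!r} fails on its own)" if culprit else ""
        raise AssemblyError(f"sanitization failed: {exc}{hint}") from exc

    radicals = sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms())
    if radicals:
        raise AssemblyError(
            f"assembly left {radicals} unpaired electron(s); check the "
            "leaving-group definitions"
        )

    atom_monomer = [a.GetIntProp("pk_mono") for a in mol.GetAtoms()]
    atom_names = [
        a.GetProp("pk_name") if a.HasProp("pk_name") else None
        for a in mol.GetAtoms()
    ]
    return MolecularGraph(mol=mol, atom_monomer=atom_monomer,
                          atom_names=atom_names)


def _find_unsanitizable(seq: Sequence) -> str | None:
    for monomer in seq.monomers:
        try:
            probe = Chem.Mol(monomer.structure)
            Chem.SanitizeMol(probe)
        except Exception:
            return monomer.symbol
    return None


def molecular_formula(graph: MolecularGraph) -> str:
    return rdMolDescriptors.CalcMolFormula(graph.mol)


# --- 2D layout -------------------------------------------------------------

def _median_bond_length(graph: MolecularGraph) -> float:
    coords = graph.coords2d()
    lengths = [
        float(np.linalg.norm(coords[b.GetBeginAtomIdx()]
                             - coords[b.GetEndAtomIdx()]))
        for b in graph.mol.GetBonds()
    ]
    return float(np.median(lengths)) if lengths else 1.5


def min_pairwise_distance(graph: MolecularGraph) -> float:
    coords = graph.coords2d()
    n = len(coords)
    if n < 2:
        return float("inf")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    dist[np.diag_indices(n)] = np.inf
    return float(dist.min())


def generate_2d_standard(graph: MolecularGraph) -> MolecularGraph:
    """Standard toolkit 2D layout (CoordGen; deterministic)."""
    mol = Chem.Mol(graph.mol)
    rdDepictor.SetPreferCoordGen(True)
    try:
        if rdDepictor.Compute2DCoords(mol) != 0:
            raise PepkitError("2D layout failed")
    finally:
        rdDepictor.SetPreferCoordGen(False)
    graph.mol = mol
    graph.layout = "standard"
    return graph


def _backbone_path(graph: MolecularGraph, seq: Sequence) -> dict[int, list[int]]:
    """Per-chain ordered backbone atom indices (N, CA, C per amino acid;
    the attachment atom for caps)."""
    paths: dict[int, list[int]] = {}
    for i, monomer in enumerate(seq.monomers):
        chain = seq.chain_of[i]
        atoms: list[int] = []
        if monomer.role == "amino_acid":
            for name in ("N", "CA", "C"):
                try:
                    atoms.append(graph.atom_index(i, name))
                except KeyError:
                    pass
        else:
            sole = sorted(monomer.r_groups)[0]
            local = monomer.r_groups[sole].attachment_atom
            for j in graph.atoms_of_monomer(i):
                if graph.atom_names[j] and graph.atom_names[j] in ("N", "C"):
                    atoms.append(j)
                    break
        paths.setdefault(chain, []).extend(atoms)
    return paths


def generate_2d_extended(
    graph: MolecularGraph,
    seq: Sequence,
    delta_min: float | None = None,
    max_iter: int = 50,
) -> MolecularGraph:
    """Extended 2D layout: backbone pinned to a zig-zag, side chains
    arranged around it.

    Peptides whose annotated bonds close a macrocycle cannot be drawn
    extended; those fall back to the standard layout with a warning.
    Residual clashes are resolved by reflecting side chains about their
    CA-CB axis for up to ``max_iter`` rounds; if clashes remain, the best
    coordinates found are kept and a warning is issued.
    """
    if any(b.kind == "annotated" for b in seq.bonds):
        warnings.warn(
            "annotated bonds close a cycle; extended layout falls back to "
            "the standard depiction"
        )
        graph = generate_2d_standard(graph)
        graph.layout = "extended"
        return graph

    mol = Chem.Mol(graph.mol)
    # 150-degree backbone zig-zag: shallow enough that a proline ring
    # (pentagon edge 108 degrees off the CA-N axis) clears the pinned
    # carbonyl on one side
    step, rise = 1.5 * np.cos(np.pi / 12), 1.5 * np.sin(np.pi / 12)
    coord_map = {}
    for chain, atoms in sorted(_backbone_path(graph, seq).items()):
        y0 = chain * 8.0
        for k, atom in enumerate(atoms):
            coord_map[atom] = Point2D(k * step, y0 + (k % 2) * rise)
    rdDepictor.Compute2DCoords(mol, coordMap=coord_map)
    graph.mol = mol
    graph.layout = "extended"
    _fix_proline_rings(graph, seq)

    if delta_min is None:
        delta_min = 0.5 * _median_bond_length(graph)
    _resolve_clashes(graph, seq, delta_min, max_iter)
    return graph


def _fix_proline_rings(graph: MolecularGraph, seq: Sequence) -> None:
    """Re-place pyrrolidine ring atoms on an ideal pentagon.

    With N, CA and C pinned to the zig-zag the depictor can fold a proline
    ring onto its own carbonyl; the three free ring atoms (CB, CG, CD) are
    moved onto the regular pentagon through CA and N, on the side away
    from the carbonyl carbon.
    """
    conf = graph.mol.GetConformer()
    for i, monomer in enumerate(seq.monomers):
        if monomer.role != "amino_acid":
            continue
        try:
            n = graph.atom_index(i, "N")
            ca = graph.atom_index(i, "CA")
            c = graph.atom_index(i, "C")
            cb = graph.atom_index(i, "CB")
            cg = graph.atom_index(i, "CG")
            cd = graph.atom_index(i, "CD")
        except KeyError:
            continue
        # proline-like: CD bonded to the backbone N closes a 5-ring
        if graph.mol.GetBondBetweenAtoms(cd, n) is None:
            continue
        p = graph.coords2d()
        edge = float(np.linalg.norm(p[ca] - p[n]))
        if edge < 1e-6:
            continue
        mid = (p[ca] + p[n]) / 2
        axis = (p[n] - p[ca]) / edge
        perp = np.array([-axis[1], axis[0]])
        radius = edge / (2 * np.sin(np.pi / 5))
        height = np.sqrt(max(radius ** 2 - (edge / 2) ** 2, 0.0))
        others = np.array([
            p[j] for j in range(len(p)) if j not in (cb, cg, cd)
        ])
        best_positions, best_clearance = None, -1.0
        stepang = 2 * np.pi / 5
        for side in (1.0, -1.0):
            center = mid + side * height * perp
            ang_ca = np.arctan2(*(p[ca] - center)[::-1])
            ang_n = np.arctan2(*(p[n] - center)[::-1])
            # walk CA -> CB -> CG -> CD -> N around the pentagon
            direction = 1.0
            if abs(_wrap(ang_ca + 4 * stepang - ang_n)) > abs(
                    _wrap(ang_ca - 4 * stepang - ang_n)):
                direction = -1.0
            positions = [
                center + radius * np.array([
                    np.cos(ang_ca + direction * k * stepang),
                    np.sin(ang_ca + direction * k * stepang),
                ])
                for k in (1, 2, 3)
            ]
            clearance = min(
                float(np.linalg.norm(others - pos, axis=1).min())
                for pos in positions
            )
            if clearance > best_clearance:
                best_clearance, best_positions = clearance, positions
        for atom, pos in zip((cb, cg, cd), best_positions):
            conf.SetAtomPosition(atom, (float(pos[0]), float(pos[1]), 0.0))


def _wrap(angle: float) -> float:
    return (angle + np.pi) % (2 * np.pi) - np.pi


def _side_chain_atoms(graph: MolecularGraph, seq: Sequence, mono: int):
    """Atoms reachable from CB without passing through CA."""
    try:
        ca = graph.atom_index(mono, "CA")
        cb = graph.atom_index(mono, "CB")
    except KeyError:
        return None
    seen = {ca, cb}
    stack = [cb]
    out = [cb]
    while stack:
        a = stack.pop()
        for nbr in graph.mol.GetAtomWithIdx(a).GetNeighbors():
            i = nbr.GetIdx()
            if i not in seen:
                seen.add(i)
                stack.append(i)
                out.append(i)
    return ca, out


def _resolve_clashes(graph: MolecularGraph, seq: Sequence,
                     delta_min: float, max_iter: int) -> None:
    conf = graph.mol.GetConformer()
    for _ in range(max_iter):
        current = min_pairwise_distance(graph)
        if current >= delta_min:
            return
        improved = False
        for mono in range(len(seq.monomers)):
            sc = _side_chain_atoms(graph, seq, mono)
            if sc is None:
                continue
            ca, atoms = sc
            cb = atoms[0]
            saved = {i: conf.GetAtomPosition(i) for i in atoms}
            _reflect(conf, ca, cb, atoms)
            if min_pairwise_distance(graph) > current + 1e-9:
                improved = True
                break
            for i, pos in saved.items():
                conf.SetAtomPosition(i, pos)
        if not improved:
            break
    if min_pairwise_distance(graph) < delta_min:
        warnings.warn(
            f"extended layout keeps a clash below {delta_min:.2f}; "
            "best-effort coordinates retained"
        )


def _reflect(conf, ca: int, cb: int, atoms: list[int]) -> None:
    """Reflect ``atoms`` across the CA-CB line (a 2D stand-in for rotating
    the side chain about that axis)."""
    p0 = np.array([conf.GetAtomPosition(ca).x, conf.GetAtomPosition(ca).y])
    p1 = np.array([conf.GetAtomPosition(cb).x, conf.GetAtomPosition(cb).y])
    d = p1 - p0
    nrm = np.linalg.norm(d)
    if nrm < 1e-9:
        return
    d = d / nrm
    for i in atoms:
        p = np.array([conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y])
        v = p - p0
        reflected = p0 + 2 * (v @ d) * d - v
        conf.SetAtomPosition(
            i, (float(reflected[0]), float(reflected[1]), 0.0)
        )


# --- export ----------------------------------------------------------------

def export_molecule(graph: MolecularGraph, format: str = "smiles") -> str:
    """Export as canonical SMILES or an SDF (V2000) record.

    The SDF record carries the residue assignment and atom names as data
    fields (``pepkit_residue_of_atom``, ``pepkit_atom_names``) so a
    re-import can recover the annotation.
    """
    if format == "smiles":
        return Chem.MolToSmiles(graph.mol)
    if format == "sdf":
        if graph.mol.GetNumConformers() == 0:
            raise PepkitError("no coordinates present; run a 2D layout first")
        mol = Chem.Mol(graph.mol)
        mol.SetProp("pepkit_residue_of_atom",
                    " ".join(str(m) for m in graph.atom_monomer))
        mol.SetProp("pepkit_atom_names",
                    " ".join(n or "?" for n in graph.atom_names))
        block = Chem.MolToMolBlock(mol, kekulize=True)
        props = []
        for key in ("pepkit_residue_of_atom", "pepkit_atom_names"):
            props.append(f">  <{key}>\n{mol.GetProp(key)}\n")
        return block + "\n".join(props) + "\n$$$$\n"
    raise PepkitError(f"unsupported export format {format!r}")
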
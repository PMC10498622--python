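"""IUPAC-style atom naming for peptide residues.

Backbone heavy atoms are named N, CA, C, O (plus OXT on a free C-terminus).
Side-chain heavy atoms are named by a breadth-first walk from the alpha
carbon, appending greek letters by distance (B, G, D, E, Z, H) and branch
numbers where a level holds more than one atom — CB, CG1/CG2, CD1, OG1 and
so on.  Hydrogens take their parent heavy atom's suffix (HB2/HB3 on a
methylene CB, HG11 on a numbered CG1 methyl).

Branch numbering must be deterministic.  Atoms within a level are ranked by
(smallest parent branch number, larger subtree first, higher atomic number
first, higher bond order to parent first, adjacency to an already-numbered
atom, canonical rank); this reproduces the PDB v3 names of all twenty
standard residues, including the fused rings of tryptophan.
"""

from __future__ import annotations

from collections import deque

from rdkit import Chem

from .errors import SequenceError

__all__ = ["greekify_monomer", "name_hydrogens", "STANDARD_HEAVY_ATOM_NAMES"]

GREEK = ["B", "G", "D", "E", "Z", "H"]

#: expected heavy-atom names of the 20 standard residues (PDB v3 convention);
#: used by tests and by geometry diagnostics
STANDARD_HEAVY_ATOM_NAMES = {
    "A": {"N", "CA", "C", "O", "CB"},
    "R": {"N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"},
    "N": {"N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"},
    "D": {"N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"},
    "C": {"N", "CA", "C", "O", "CB", "SG"},
    "E": {"N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"},
    "Q": {"N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"},
    "G": {"N", "CA", "C", "O"},
    "H": {"N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"},
    "I": {"N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"},
    "L": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"},
    "K": {"N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"},
    "M": {"N", "CA", "C", "O", "CB", "CG", "SD", "CE"},
    "F": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "P": {"N", "CA", "C", "O", "CB", "CG", "CD"},
    "S": {"N", "CA", "C", "O", "CB", "OG"},
    "T": {"N", "CA", "C", "O", "CB", "OG1", "CG2"},
    "W": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3",
          "CZ2", "CZ3", "CH2"},
    "Y": {"N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ",
          "OH"},
    "V": {"N", "CA", "C", "O", "CB", "CG1", "CG2"},
}


def _subtree_size(mol, root, blocked, walkable):
    seen = {root} | blocked
    queue = deque([root])
    size = 0
    while queue:
        a = queue.popleft()
        size += 1
        for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
            i = nbr.GetIdx()
            if i not in seen and i in walkable:
                seen.add(i)
                queue.append(i)
    return size


def _walk_element(mol, idx, oh_dummies):
    """Element symbol used for naming; OH-leaving dummies count as oxygen."""
    if idx in oh_dummies:
        return "O"
    return mol.GetAtomWithIdx(idx).GetSymbol().upper()


def _walk_atomic_num(mol, idx, oh_dummies):
    if idx in oh_dummies:
        return 8
    return mol.GetAtomWithIdx(idx).GetAtomicNum()


def greekify_monomer(monomer) -> dict[int, str]:
    """Name the heavy atoms of one monomer structure.

    Returns a map from atom index (in the monomer's own structure, dummy
    placeholders excluded) to name.  Amino acids get the full backbone +
    greek side-chain treatment; caps get short conventional names (acetyl:
    C/O/CH3-style; amide: N).
    """
    mol = monomer.structure
    names: dict[int, str] = {}
    canon = list(Chem.CanonicalRankAtoms(mol, breakTies=True))
    symclass = list(Chem.CanonicalRankAtoms(mol, breakTies=False))

    if monomer.role == "cap":
        return _name_cap(monomer, canon)

    r1 = monomer.r_groups.get(1)
    r2 = monomer.r_groups.get(2)
    if r1 is None or r2 is None:
        raise SequenceError(
            f"monomer {monomer.symbol!r}: amino acid must expose R1 and R2"
        )
    n_idx = r1.attachment_atom
    c_idx = r2.attachment_atom
    n_nbrs = {a.GetIdx() for a in mol.GetAtomWithIdx(n_idx).GetNeighbors()}
    c_nbrs = {a.GetIdx() for a in mol.GetAtomWithIdx(c_idx).GetNeighbors()}
    shared = [
        i for i in (n_nbrs & c_nbrs)
        if mol.GetAtomWithIdx(i).GetAtomicNum() > 1
    ]
    if not shared:
        raise SequenceError(
            f"monomer {monomer.symbol!r}: backbone N and C share no alpha "
            "carbon (disconnected backbone)"
        )
    ca_idx = min(shared, key=lambda i: canon[i])
    names[n_idx] = "N"
    names[ca_idx] = "CA"
    names[c_idx] = "C"
    for nbr in mol.GetAtomWithIdx(c_idx).GetNeighbors():
        if (nbr.GetAtomicNum() == 8
                and mol.GetBondBetweenAtoms(c_idx, nbr.GetIdx()).GetBondType()
                == Chem.BondType.DOUBLE):
            names[nbr.GetIdx()] = "O"
            break

    # side-chain dummies whose leaving group is OH act as the oxygen they
    # will become (e.g. the second carboxyl oxygen of Asp/Glu); H-leaving
    # dummies behave like hydrogens and are skipped
    oh_dummies = {
        g.dummy_atom
        for idx, g in monomer.r_groups.items()
        if idx >= 3 and g.leaving_group == "OH"
    }
    walkable = {
        a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1
    } | oh_dummies

    blocked = {n_idx, c_idx}
    _greek_walk(mol, ca_idx, blocked, names, canon, symclass, oh_dummies,
                walkable)

    # anything left (e.g. an N-methyl carbon) gets element + counter
    used = set(names.values())
    counters: dict[str, int] = {}
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        if atom.GetAtomicNum() in (0, 1) or i in names:
            continue
        el = atom.GetSymbol().upper()
        if el == "C" and "CN" not in used and any(
            n.GetIdx() == n_idx for n in atom.GetNeighbors()
        ):
            names[i] = "CN"  # N-methyl carbon
            used.add("CN")
            continue
        k = counters.get(el, 0) + 1
        while f"{el}{k}" in used:
            k += 1
        counters[el] = k
        names[i] = f"{el}{k}"
        used.add(names[i])
    return names


def _name_cap(monomer, canon) -> dict[int, str]:
    mol = monomer.structure
    names: dict[int, str] = {}
    sole = next(iter(sorted(monomer.r_groups)))
    att = monomer.r_groups[sole].attachment_atom
    att_atom = mol.GetAtomWithIdx(att)
    if att_atom.GetAtomicNum() == 7:
        names[att] = "N"
    else:
        names[att] = "C"
        for nbr in att_atom.GetNeighbors():
            if (nbr.GetAtomicNum() == 8
                    and mol.GetBondBetweenAtoms(att, nbr.GetIdx()).GetBondType()
                    == Chem.BondType.DOUBLE):
                names[nbr.GetIdx()] = "O"
    used = set(names.values())
    counters: dict[str, int] = {}
    for atom in sorted(mol.GetAtoms(), key=lambda a: canon[a.GetIdx()]):
        i = atom.GetIdx()
        if atom.GetAtomicNum() in (0, 1) or i in names:
            continue
        el = atom.GetSymbol().upper()
        # methyl directly on the carbonyl of an acetyl-like cap
        if el == "C" and "CH3" not in used and any(
            n.GetIdx() in names and names[n.GetIdx()] == "C"
            for n in atom.GetNeighbors()
        ):
            names[i] = "CH3"
            used.add("CH3")
            continue
        k = counters.get(el, 0) + 1
        while f"{el}{k}" in used:
            k += 1
        counters[el] = k
        names[i] = f"{el}{k}"
        used.add(names[i])
    return names


def _greek_walk(mol, ca_idx, blocked, names, canon, symclass, oh_dummies,
                walkable) -> None:
    """BFS from CA assigning greek-letter names with branch numbers."""
    numbers: dict[int, int | None] = {}  # atom -> branch number (None = none)
    level_atoms = [ca_idx]
    visited = {ca_idx} | set(blocked)
    parents: dict[int, list[int]] = {}
    depth = 0
    while True:
        nxt: list[int] = []
        for a in level_atoms:
            for nbr in mol.GetAtomWithIdx(a).GetNeighbors():
                i = nbr.GetIdx()
                if i in visited or i not in walkable:
                    continue
                parents.setdefault(i, []).append(a)
                if i not in nxt:
                    nxt.append(i)
        visited.update(nxt)
        if not nxt:
            break
        if depth >= len(GREEK):
            # beyond eta: fall back to element+counter via caller's cleanup
            break
        letter = GREEK[depth]
        _assign_level(mol, nxt, parents, numbers, blocked, canon, symclass,
                      oh_dummies, walkable)
        for i in nxt:
            el = _walk_element(mol, i, oh_dummies)
            num = numbers[i]
            names[i] = f"{el}{letter}" + (str(num) if num is not None else "")
        level_atoms = nxt
        depth += 1


def _assign_level(mol, atoms, parents, numbers, blocked, canon, symclass,
                  oh_dummies, walkable) -> None:
    """Branch-number one BFS level.

    Numbers propagate along branches (CD1 -> CE1); a level whose atoms all
    inherit distinct parent numbers keeps them.  A single atom closing a
    ring between symmetry-equivalent branches (Phe/Tyr CZ) stays
    unnumbered; closing between inequivalent branches (Trp CH2) inherits
    the smaller branch number.  Levels without inheritable numbers are
    ranked 1..k by subtree size, atomic number, bond order and adjacency.
    """
    def parent_nums(i):
        return sorted({
            numbers[p] for p in parents[i] if numbers.get(p) is not None
        })

    if len(atoms) == 1:
        i = atoms[0]
        pnums = parent_nums(i)
        if not pnums:
            numbers[i] = None
        elif len(pnums) == 1:
            numbers[i] = pnums[0]
        else:
            classes = {symclass[p] for p in parents[i]}
            numbers[i] = None if len(classes) == 1 else pnums[0]
        return

    inherited = [parent_nums(i) for i in atoms]
    flat = [p[0] for p in inherited if len(p) == 1]
    if len(flat) == len(atoms) and len(set(flat)) == len(flat):
        for i, num in zip(atoms, flat):
            numbers[i] = num
        return

    def bond_order(i):
        return max(
            mol.GetBondBetweenAtoms(i, p).GetBondTypeAsDouble()
            for p in parents[i]
        )

    remaining = list(atoms)
    ordered: list[int] = []
    while remaining:
        def sort_key(i):
            placed_neighbor = min(
                (ordered.index(n.GetIdx()) for n in
                 mol.GetAtomWithIdx(i).GetNeighbors()
                 if n.GetIdx() in ordered),
                default=len(atoms),
            )
            pnums = parent_nums(i)
            return (
                pnums[0] if pnums else 0,
                -_subtree_size(mol, i, set(parents[i]) | set(blocked),
                               walkable),
                -_walk_atomic_num(mol, i, oh_dummies),
                -bond_order(i),
                placed_neighbor,
                canon[i],
            )
        best = min(remaining, key=sort_key)
        ordered.append(best)
        remaining.remove(best)
    for rank, i in enumerate(ordered, start=1):
        numbers[i] = rank


def name_hydrogens(
    mol: Chem.Mol,
    heavy_names: dict[int, str],
    n_terminal_n: set[int] | None = None,
) -> dict[int, str]:
    """Name explicit hydrogens from their parent heavy atom's name.

    ``heavy_names`` maps atom indices of ``mol`` (which must carry explicit
    hydrogens) to heavy-atom names.  The amide hydrogen on a mid-chain
    backbone N is named H; hydrogens of a free N-terminal amine are
    H1/H2/H3 (``n_terminal_n`` lists those nitrogen atom indices).
    Methylene/methyl hydrogens on an unnumbered heavy atom X? are numbered
    2,3 (two H) or 1,2,3 (three H); a single hydrogen drops the number
    except on numbered parents (OG1 -> HG1).
    """
    n_terminal_n = n_terminal_n or set()
    h_names: dict[int, str] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1:
            continue
        idx = atom.GetIdx()
        name = heavy_names.get(idx)
        if name is None:
            continue
        hs = sorted(
            n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1
        )
        if not hs:
            continue
        if name == "N":
            if idx in n_terminal_n:
                for k, h in enumerate(hs, start=1):
                    h_names[h] = f"H{k}"
            elif len(hs) == 1:
                h_names[hs[0]] = "H"
            else:
                for k, h in enumerate(hs, start=1):
                    h_names[h] = f"H{k}"
            continue
        suffix = name[1:] if name[0].isalpha() else name
        if name == "CA":
            suffix = "A"
        if name == "OXT":
            h_names[hs[0]] = "HXT"
            continue
        if suffix and suffix[-1].isdigit():
            for k, h in enumerate(hs, start=1):
                h_names[h] = f"H{suffix}{k}" if len(hs) > 1 else f"H{suffix}"
            continue
        if len(hs) == 1:
            h_names[hs[0]] = f"H{suffix}" if suffix else "H"
        elif len(hs) == 2:
            h_names[hs[0]], h_names[hs[1]] = f"H{suffix}2", f"H{suffix}3"
        else:
            for k, h in enumerate(hs, start=1):
                h_names[h] = f"H{suffix}{k}"
    return h_names
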
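"""Molecule assembly chemistry, topology and 2D layout contracts."""

import warnings

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from pepkit.errors import AssemblyError
from pepkit.molecule import (
    assemble_molecule,
    export_molecule,
    generate_2d_extended,
    generate_2d_standard,
    min_pairwise_distance,
    molecular_formula,
)
from pepkit.molecule import _backbone_path, _median_bond_length
from pepkit.sequence import build_sequence

from .conftest import NOTATION_EXAMPLES, OXYTOCIN_BILN

ALL_BILN = [row[0] for row in NOTATION_EXAMPLES]


def _formula_counts(formula: str) -> dict:
    import re
    counts = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def _free_monomer_formula(library, symbol):
    seq = build_sequence(symbol, library)
    return _formula_counts(molecular_formula(assemble_molecule(seq)))


class TestAssemblyChemistry:
    def test_free_glycine(self, library):
        graph = assemble_molecule(build_sequence("G", library))
        assert molecular_formula(graph) == "C2H5NO2"

    def test_diglycine_condensation(self, library):
        graph = assemble_molecule(build_sequence("G-G", library))
        assert export_molecule(graph, "smiles") == \
            Chem.CanonSmiles("NCC(=O)NCC(=O)O")
        assert molecular_formula(graph) == "C4H8N2O3"

    def test_acetyl_glycinamide(self, library):
        graph = assemble_molecule(build_sequence("ac-G-am", library))
        assert export_molecule(graph, "smiles") == \
            Chem.CanonSmiles("CC(=O)NCC(N)=O")

    @pytest.mark.parametrize("biln,n_water", [
        ("A-A-A", 2),
        ("P-E-P-T-I-D-E", 6),
        ("G-L-V-K-T", 4),
    ])
    def test_mass_conservation_linear(self, library, biln, n_water):
        symbols = biln.split("-")
        total = {}
        for s in symbols:
            for el, k in _free_monomer_formula(library, s).items():
                total[el] = total.get(el, 0) + k
        total["H"] -= 2 * n_water
        total["O"] -= n_water
        graph = assemble_molecule(build_sequence(biln, library))
        assert _formula_counts(molecular_formula(graph)) == total

    def test_mass_conservation_disulfide(self, library):
        # 4 amide bonds lose H2O each; the disulfide loses H2
        total = {}
        for s in ["C", "A", "A", "A", "C"]:
            for el, k in _free_monomer_formula(library, s).items():
                total[el] = total.get(el, 0) + k
        total["H"] -= 2 * 4 + 2
        total["O"] -= 4
        graph = assemble_molecule(
            build_sequence("C(1,3)-A-A-A-C(1,3)", library))
        assert _formula_counts(molecular_formula(graph)) == total

    def test_mass_conservation_random_peptides(self, library):
        rng = np.random.default_rng(11)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            n = int(rng.integers(2, 8))
            symbols = [letters[i] for i in rng.integers(0, 20, n)]
            total = {}
            for s in symbols:
                for el, k in _free_monomer_formula(library, s).items():
                    total[el] = total.get(el, 0) + k
            total["H"] -= 2 * (n - 1)
            total["O"] -= n - 1
            graph = assemble_molecule(
                build_sequence("-".join(symbols), library))
            assert _formula_counts(molecular_formula(graph)) == total

    def test_unvalidated_sequence_rejected(self, library):
        seq = build_sequence("A-A", library)
        seq.bonds.clear()
        with pytest.raises(AssemblyError):
            assemble_molecule(seq)


class TestTopology:
    def test_oxytocin_disulfide_macrocycle(self, library):
        graph = assemble_molecule(build_sequence(OXYTOCIN_BILN, library))
        ss_bonds = [
            b for b in graph.mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() == 16
            and b.GetEndAtom().GetAtomicNum() == 16
        ]
        assert len(ss_bonds) == 1
        assert len(set(graph.atom_monomer)) == 9
        ring_info = graph.mol.GetRingInfo()
        ss_bond = ss_bonds[0]
        assert ring_info.NumBondRings(ss_bond.GetIdx()) == 1

    def test_head_to_tail_macrocycle_ring(self, library):
        graph = assemble_molecule(
            build_sequence("C(1,1)-A-A-A-C(1,2)", library))
        # the macrocycle is the only ring
        assert rdMolDescriptors.CalcNumRings(graph.mol) == 1
        # no free termini: no primary amine N and no carboxylic acid
        mol = graph.mol
        assert not mol.HasSubstructMatch(Chem.MolFromSmarts("[NX3;H2]"))
        assert not mol.HasSubstructMatch(
            Chem.MolFromSmarts("C(=O)[OX2H1]"))

    def test_chain_order_invariance(self, library):
        a = assemble_molecule(
            build_sequence("A-G-Q.K-L-V", library))
        b = assemble_molecule(
            build_sequence("K-L-V.A-G-Q", library))
        assert export_molecule(a, "smiles") == export_molecule(b, "smiles")


class TestLayout2D:
    @pytest.mark.parametrize("biln", ALL_BILN)
    def test_standard_layout_clash_free(self, library, biln):
        graph = generate_2d_standard(
            assemble_molecule(build_sequence(biln, library)))
        assert graph.mol.GetNumConformers() == 1
        assert min_pairwise_distance(graph) >= \
            0.5 * _median_bond_length(graph)

    @pytest.mark.parametrize("biln", ALL_BILN)
    def test_extended_layout_clash_free(self, library, biln):
        seq = build_sequence(biln, library)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = generate_2d_extended(assemble_molecule(seq), seq)
        assert min_pairwise_distance(graph) >= \
            0.5 * _median_bond_length(graph)

    def test_standard_layout_deterministic(self, library):
        seq = build_sequence("P-E-P-T-I-D-E", library)
        a = generate_2d_standard(assemble_molecule(seq))
        b = generate_2d_standard(assemble_molecule(seq))
        assert np.allclose(a.coords2d(), b.coords2d())

    def test_extended_backbone_is_extended(self, library):
        seq = build_sequence("P-E-P-T-I-D-E", library)
        graph = generate_2d_extended(assemble_molecule(seq), seq)
        backbone = _backbone_path(graph, seq)[0]
        coords = graph.coords2d()[backbone]
        contour = float(np.linalg.norm(np.diff(coords, axis=0),
                                       axis=1).sum())
        end_to_end = float(np.linalg.norm(coords[-1] - coords[0]))
        assert end_to_end / contour >= 0.8

    def test_single_residue_trivially_clash_free(self, library):
        seq = build_sequence("A", library)
        graph = generate_2d_extended(assemble_molecule(seq), seq)
        assert min_pairwise_distance(graph) >= \
            0.5 * _median_bond_length(graph)


class TestExport:
    def test_smiles_stable_across_runs(self, library):
        a = assemble_molecule(build_sequence("G-G", library))
        b = assemble_molecule(build_sequence("G-G", library))
        assert export_molecule(a) == export_molecule(b)

    def test_sdf_round_trip_counts(self, library):
        seq = build_sequence("ac-D-T-H-F-E-I-A-am", library)
        graph = generate_2d_standard(assemble_molecule(seq))
        text = export_molecule(graph, "sdf")
        mol = Chem.MolFromMolBlock(text)
        assert mol.GetNumAtoms() == graph.num_atoms
        assert mol.GetNumBonds() == graph.mol.GetNumBonds()
        assert "pepkit_residue_of_atom" in text

    def test_unsupported_format_rejected(self, library):
        graph = assemble_molecule(build_sequence("G", library))
        with pytest.raises(Exception, match="format"):
            export_molecule(graph, "mol2")
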
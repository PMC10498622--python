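"""Distance restraints, seeded embedding, PDB export and diagnostics."""

import io

import numpy as np
import pytest
from Bio.PDB import PDBParser

from pepkit.conformer import (
    DistanceBounds,
    RestraintConfig,
    build_distance_bounds,
    check_ss_geometry,
    embed_conformer,
    write_pdb,
)
from pepkit.errors import PepkitError, SSLengthError
from pepkit.molecule import assemble_molecule
from pepkit.naming import STANDARD_HEAVY_ATOM_NAMES
from pepkit.sequence import build_sequence

from .conftest import OXYTOCIN_BILN


@pytest.fixture(scope="module")
def octa_ala(library):
    seq = build_sequence("A-A-A-A-A-A-A-A", library)
    return seq, assemble_molecule(seq)


class TestDistanceBounds:
    def test_coil_yields_no_restraints(self, octa_ala):
        seq, graph = octa_ala
        assert len(build_distance_bounds(graph, seq, "--------")) == 0

    def test_full_helix_pair_count(self, octa_ala):
        # i -> i+4 over an 8-residue run: 4 O-N pairs plus 4 CA-CA pairs
        seq, graph = octa_ala
        bounds = build_distance_bounds(graph, seq, "HHHHHHHH")
        assert len(bounds) == 8

    def test_short_helix_run_unrestrained(self, library):
        seq = build_sequence("A-A-A-A", library)
        graph = assemble_molecule(seq)
        assert len(build_distance_bounds(graph, seq, "HHH-")) == 0

    def test_strand_run_pair_count(self, library):
        seq = build_sequence("V-T-V-T-V", library)
        graph = assemble_molecule(seq)
        bounds = build_distance_bounds(graph, seq, "EEEEE")
        assert len(bounds) == 3  # CA(i)-CA(i+2), i = 0..2

    def test_g_inside_helix_run_counts(self, octa_ala):
        seq, graph = octa_ala
        # H-dominated run with a 3/10 entry is restrained end to end
        assert len(build_distance_bounds(graph, seq, "HHHGHHHH")) == 8
        # a standalone 3/10 run is left unrestrained
        assert len(build_distance_bounds(graph, seq, "GGGGG---")) == 0

    def test_ss_length_mismatch(self, octa_ala):
        seq, graph = octa_ala
        with pytest.raises(SSLengthError):
            build_distance_bounds(graph, seq, "HHHH")

    def test_caps_carry_no_category(self, library):
        seq = build_sequence("ac-A-A-A-A-A-am", library)
        graph = assemble_molecule(seq)
        bounds = build_distance_bounds(graph, seq, "HHHHH")
        assert len(bounds) == 2  # single i,i+4 window over five residues


class TestEmbedding:
    def test_seeded_runs_are_bit_identical(self, octa_ala):
        seq, graph = octa_ala
        bounds = build_distance_bounds(graph, seq, "HHHHHHHH")
        a = embed_conformer(graph, bounds, seed=7)
        b = embed_conformer(graph, bounds, seed=7)
        assert np.array_equal(a.coords3d, b.coords3d)

    def test_unrestrained_bonded_distances_sane(self, octa_ala):
        _, graph = octa_ala
        conf = embed_conformer(graph, None, seed=7)
        for bond in conf.mol.GetBonds():
            d = np.linalg.norm(
                conf.coords3d[bond.GetBeginAtomIdx()]
                - conf.coords3d[bond.GetEndAtomIdx()]
            )
            assert 0.7 <= d <= 2.5

    @pytest.mark.parametrize("seed", [1, 7, 2023])
    def test_helix_restraints_satisfied(self, octa_ala, seed):
        seq, graph = octa_ala
        bounds = build_distance_bounds(graph, seq, "HHHHHHHH")
        conf = embed_conformer(graph, bounds, seed=seed)
        report = check_ss_geometry(conf, graph, seq, "HHHHHHHH")
        on_pairs = report.pairs[
            (report.pairs.name_a == "O") | (report.pairs.name_b == "O")
        ]
        assert len(on_pairs) == 4
        satisfied = (
            (on_pairs.distance >= 2.2) & (on_pairs.distance <= 3.6)
        ).mean()
        assert satisfied >= 0.8

    def test_injection_never_loosens(self, octa_ala):
        # a window far wider than the engine default would loosen the
        # bounds; the implementation clamps, so the effective interval can
        # only shrink, and an infeasible clamp errors out
        seq, graph = octa_ala
        bad = DistanceBounds()
        bad.add(0, graph.num_atoms - 1, 0.8, 0.9)  # below vdW lower bound
        with pytest.raises(PepkitError, match="incompatible"):
            embed_conformer(graph, bad, seed=7)

    def test_provenance_recorded(self, octa_ala):
        seq, graph = octa_ala
        conf = embed_conformer(graph, None, seed=3)
        assert conf.provenance["seed"] == 3
        assert conf.provenance["n_restraints"] == 0


class TestWritePdb:
    def test_trialanine_names_and_codes(self, library):
        seq = build_sequence("A-A-A", library)
        graph = assemble_molecule(seq)
        conf = embed_conformer(graph, None, seed=5)
        structure = PDBParser(QUIET=True).get_structure(
            "x", io.StringIO(write_pdb(conf, graph, seq)))
        residues = list(structure.get_residues())
        assert [r.get_resname() for r in residues] == ["ALA"] * 3
        for res in residues:
            names = {a.get_name() for a in res}
            assert {"N", "CA", "C", "O", "CB"} <= names

    def test_oxytocin_disulfide_conect(self, library):
        seq = build_sequence(OXYTOCIN_BILN, library)
        graph = assemble_molecule(seq)
        conf = embed_conformer(graph, None, seed=5)
        pdb = write_pdb(conf, graph, seq)
        conect = [ln for ln in pdb.splitlines() if ln.startswith("CONECT")]
        assert len(conect) == 2  # both directions of the single S-S bond
        serials = {int(tok) for ln in conect for tok in ln.split()[1:]}
        atom_lines = [ln for ln in pdb.splitlines()
                      if ln.startswith(("ATOM", "HETATM"))]
        sg_serials = {
            int(ln[6:11]) for ln in atom_lines if ln[12:16].strip() == "SG"
        }
        assert serials <= sg_serials

    def test_round_trip_counts(self, library):
        seq = build_sequence("ac-D-T-H-F-E-I-A-am", library)
        graph = assemble_molecule(seq)
        conf = embed_conformer(graph, None, seed=5)
        structure = PDBParser(QUIET=True).get_structure(
            "x", io.StringIO(write_pdb(conf, graph, seq)))
        assert len(list(structure.get_residues())) == 9
        assert len(list(structure.get_atoms())) == conf.mol.GetNumAtoms()

    def test_standard_residue_heavy_names_match_convention(self, library):
        biln = "-".join(sorted(STANDARD_HEAVY_ATOM_NAMES))
        seq = build_sequence(biln, library)
        graph = assemble_molecule(seq)
        conf = embed_conformer(graph, None, seed=5)
        structure = PDBParser(QUIET=True).get_structure(
            "x", io.StringIO(write_pdb(conf, graph, seq)))
        residues = list(structure.get_residues())
        for letter, res in zip(sorted(STANDARD_HEAVY_ATOM_NAMES), residues):
            heavy = {a.get_name() for a in res
                     if a.element != "H"}
            expected = set(STANDARD_HEAVY_ATOM_NAMES[letter])
            if letter == sorted(STANDARD_HEAVY_ATOM_NAMES)[0]:
                pass  # N-terminal residue has no extra heavy atoms
            if letter == sorted(STANDARD_HEAVY_ATOM_NAMES)[-1]:
                expected = expected | {"OXT"}
            # Asp/Glu keep their side-chain capping oxygen
            expected |= {"OD2", "OE2"} & heavy
            assert heavy == expected, letter

    def test_two_chains_lettered(self, library):
        seq = build_sequence("A-G-Q.K-L-V", library)
        graph = assemble_molecule(seq)
        conf = embed_conformer(graph, None, seed=5)
        structure = PDBParser(QUIET=True).get_structure(
            "x", io.StringIO(write_pdb(conf, graph, seq)))
        chains = [c.id for c in structure.get_chains()]
        assert chains == ["A", "B"]


class TestDiagnostics:
    def test_unrestrained_coil_report(self, octa_ala):
        seq, graph = octa_ala
        conf = embed_conformer(graph, None, seed=7)
        report = check_ss_geometry(conf, graph, seq, "--------")
        assert len(report.pairs) == 0
        assert len(report.phi_psi) == 8
        # interior residues get both dihedrals
        interior = report.phi_psi.iloc[1:-1]
        assert interior.phi.notna().all() and interior.psi.notna().all()

    def test_row_count_matches_restraints(self, octa_ala):
        seq, graph = octa_ala
        bounds = build_distance_bounds(graph, seq, "HHHHHHHH")
        conf = embed_conformer(graph, bounds, seed=7)
        report = check_ss_geometry(conf, graph, seq, "HHHHHHHH")
        assert len(report.pairs) == len(bounds.pairs)
        assert 0.0 <= report.satisfied_fraction <= 1.0
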
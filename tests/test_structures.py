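"""Structure I/O, secondary structure, superposition and contact counting."""

import numpy as np
import pytest

from idrfold import (
    StructureModel,
    assign_ss3,
    gen_beta_sheet,
    gen_extended_structure,
    gen_helix_structure,
    hydrophobic_contacts,
    plddt_from_bfactor,
    read_structure,
    ss_content_by_bin,
    superpose_rmsd,
    write_pdb,
)
from idrfold.structures import StructureParseError
from idrfold.synthetic import _rotation_matrix, replace_coords


@pytest.fixture(scope="module")
def helix20():
    return gen_helix_structure(20)


class TestReadWrite:
    def test_pdb_round_trip(self, tmp_path, helix20):
        path = tmp_path / "helix.pdb"
        write_pdb(helix20, path)
        model = read_structure(path)
        assert len(model) == len(helix20)
        assert model.n_residues == 20
        np.testing.assert_allclose(model.coords, helix20.coords, atol=1e-3)

    def test_multi_model_selection(self, tmp_path, helix20):
        path = tmp_path / "single.pdb"
        write_pdb(helix20, path)
        atoms = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
        body = "\n".join(atoms)
        multi = tmp_path / "multi.pdb"
        multi.write_text(
            f"MODEL        1\n{body}\nENDMDL\nMODEL        2\n{body}\nENDMDL\nEND\n"
        )
        m2 = read_structure(multi, model_number=2)
        assert m2.model_number == 2 and len(m2) == len(helix20)
        with pytest.raises(KeyError):
            read_structure(multi, model_number=9)

    def test_no_atoms_is_an_error(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(StructureParseError):
            read_structure(empty)


class TestPlddtExtraction:
    def test_bfactor_pass_through(self, tmp_path):
        model = gen_helix_structure(4)
        values = [35.2, 88.0, 91.5, 70.0]
        for i in range(len(model)):
            model.b_factors[i] = values[model.res_ids[i] - 1]
        np.testing.assert_allclose(plddt_from_bfactor(model), values)

    def test_out_of_range_bfactor_rejected(self):
        model = gen_helix_structure(4)
        model.b_factors[:] = 101.0
        with pytest.raises(ValueError, match="outside pLDDT range"):
            plddt_from_bfactor(model)

    def test_missing_ca_names_residue(self):
        model = gen_helix_structure(4)
        keep = ~((model.res_ids == 2) & (model.atom_names == "CA"))
        trimmed = StructureModel(
            chain_id=model.chain_id,
            res_ids=model.res_ids[keep],
            res_names=model.res_names[keep],
            atom_names=model.atom_names[keep],
            elements=model.elements[keep],
            coords=model.coords[keep],
            b_factors=model.b_factors[keep],
        )
        with pytest.raises(ValueError, match="residue 2"):
            plddt_from_bfactor(trimmed)


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self, helix20):
        ss = assign_ss3(helix20)
        assert len(ss) == 20
        interior = ss[2:18]
        assert interior.count("H") / len(interior) >= 0.8

    def test_extended_chain_all_coil(self):
        assert set(assign_ss3(gen_extended_structure(12))) == {"C"}

    def test_antiparallel_sheet_interior_is_E(self):
        sheet = gen_beta_sheet(8)
        ss = assign_ss3(sheet)
        # both strands' interiors carry strand assignments
        assert ss[1:7].count("E") >= 4
        assert ss[9:15].count("E") >= 4

    def test_atom_order_within_residues_irrelevant(self, helix20):
        perm = []
        for rid in helix20.residue_order:
            idx = list(helix20.residue_atoms(rid))
            perm.extend(idx[::-1])
        shuffled = StructureModel(
            chain_id=helix20.chain_id,
            res_ids=helix20.res_ids[perm],
            res_names=helix20.res_names[perm],
            atom_names=helix20.atom_names[perm],
            elements=helix20.elements[perm],
            coords=helix20.coords[perm],
            b_factors=helix20.b_factors[perm],
        )
        assert assign_ss3(shuffled) == assign_ss3(helix20)


class TestSSContentByBin:
    def test_single_bin_all_helix(self):
        table = ss_content_by_bin("HHHH", [95, 95, 95, 95])
        assert list(table.index) == ["very_confident"]
        assert table.loc["very_confident", "pct_H"] == 100.0

    def test_two_bin_split(self):
        table = ss_content_by_bin("HCCC", [95, 40, 40, 40])
        assert table.loc["very_low", "pct_C"] == 100.0
        assert table.loc["very_confident", "pct_H"] == 100.0

    def test_percentages_sum_to_100(self, rng):
        ss = "".join(rng.choice(list("HEC"), size=200))
        plddt = rng.uniform(0, 100, size=200)
        table = ss_content_by_bin(ss, plddt)
        sums = table[["pct_H", "pct_E", "pct_C"]].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss_content_by_bin("HH", [50.0])


class TestSuperposition:
    def test_self_superposition_zero(self, helix20):
        res = superpose_rmsd(helix20, helix20)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self, helix20, rng):
        for _ in range(5):
            axis = rng.normal(size=3)
            R = _rotation_matrix(axis, float(rng.uniform(0, 360)))
            shift = rng.normal(scale=20, size=3)
            moved = replace_coords(helix20, helix20.coords @ R.T + shift)
            res = superpose_rmsd(helix20, moved)
            assert res.rmsd < 1e-6
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_reflection_not_allowed(self, helix20):
        mirrored = replace_coords(helix20, helix20.coords * np.array([1, 1, -1.0]))
        res = superpose_rmsd(helix20, mirrored)
        # a proper rotation cannot undo a reflection of a chiral helix
        assert res.rmsd > 0.5
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_known_rmsd_from_perturbation(self, helix20, rng):
        # displacing every atom by a fixed-norm random vector bounds the RMSD
        noise = rng.normal(size=helix20.coords.shape)
        noise *= 0.5 / np.linalg.norm(noise, axis=1, keepdims=True)
        moved = replace_coords(helix20, helix20.coords + noise)
        res = superpose_rmsd(helix20, moved)
        assert 0 < res.rmsd <= 0.5 + 1e-9

    def test_unpairable_atoms_reported(self, helix20):
        shorter = gen_helix_structure(10)
        with pytest.raises(ValueError, match="no partner"):
            superpose_rmsd(helix20, shorter)

    def test_residue_selection_and_offset(self, helix20):
        renumbered = replace_coords(helix20, helix20.coords, first_res_id=101)
        res = superpose_rmsd(
            helix20, renumbered, residue_selection=range(5, 16), residue_offset=100
        )
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_atoms == 11 * 4


def _toy_two_atom_model(distance: float) -> StructureModel:
    # two isolated methyl-like carbons in different residues
    return StructureModel(
        chain_id="A",
        res_ids=np.array([1, 2]),
        res_names=np.array(["LEU", "LEU"], dtype=object),
        atom_names=np.array(["CD1", "CD1"], dtype=object),
        elements=np.array(["C", "C"], dtype=object),
        coords=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
        b_factors=np.array([100.0, 100.0]),
    )


class TestHydrophobicContacts:
    def test_single_pair_within_threshold(self):
        report = hydrophobic_contacts(_toy_two_atom_model(4.4), 1, (1, 5))
        assert report.count == 1

    def test_pair_beyond_threshold(self):
        report = hydrophobic_contacts(_toy_two_atom_model(4.6), 1, (1, 5))
        assert report.count == 0

    def test_monotone_in_threshold(self):
        m = _toy_two_atom_model(4.0)
        counts = [
            hydrophobic_contacts(m, 1, (1, 5), threshold=t).count
            for t in (3.0, 4.0, 4.5, 6.0)
        ]
        assert counts == sorted(counts)

    def test_polar_neighbor_disqualifies_carbon(self):
        # a carbon bonded to an oxygen is not apolar
        model = StructureModel(
            chain_id="A",
            res_ids=np.array([1, 1, 2]),
            res_names=np.array(["SER", "SER", "LEU"], dtype=object),
            atom_names=np.array(["CB", "OG", "CD1"], dtype=object),
            elements=np.array(["C", "O", "C"], dtype=object),
            coords=np.array([[0.0, 0, 0], [1.4, 0, 0], [0.0, 4.0, 0]]),
            b_factors=np.zeros(3),
        )
        assert hydrophobic_contacts(model, 1, (1, 5)).count == 0

    def test_missing_focal_residue(self):
        with pytest.raises(KeyError):
            hydrophobic_contacts(_toy_two_atom_model(4.0), 99, (1, 5))

    def test_backbone_atoms_excluded_from_focal_side_chain(self):
        helix = gen_helix_structure(10)
        report = hydrophobic_contacts(helix, 5, (1, 10))
        assert report.count == 0  # backbone-only model has no side-chain atoms
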
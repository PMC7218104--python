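"""Structure loading, site distances and SASA burial classification."""

import math

import numpy as np
import pytest
import biotite.structure as struc
from biotite.structure.info import vdw_radius_single

from consdesign.structure_annot import (
    StructureError,
    StructureModel,
    annotate_position,
    burial_class,
    classify_copper_sites,
    load_structure,
    relative_accessibility,
    site_distance,
    write_annotation_table,
)
from consdesign.synthetic_data import generate_toy_structure


def toy_model(tmp_path, planted, n_residues=1, seed=0):
    toy = generate_toy_structure(n_residues, planted, seed=seed)
    path = tmp_path / "toy.pdb"
    path.write_text(toy.pdb_text)
    return load_structure(path, toy.site_spec)


def make_model(coords, elements, res_ids, hetero, res_names=None, sites=None):
    """In-memory StructureModel without file round-tripping (full precision)."""
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.asarray(res_ids)
    arr.res_name = np.array(res_names or ["ALA"] * n)
    arr.atom_name = np.array(["CA"] * n)
    arr.element = np.array(elements)
    arr.hetero = np.asarray(hetero)
    model = StructureModel(atoms=arr, named_sites={})
    for label, mask in (sites or {}).items():
        model.named_sites[label] = arr[np.asarray(mask)]
    return model


class TestLoadStructure:
    def test_reads_minimal_synthetic_pdb(self, tmp_path):
        model = toy_model(tmp_path, [(1, "siteA", 5.0)])
        assert model.atoms.array_length() == 2
        assert set(model.named_sites) == {"siteA"}

    def test_empty_site_selection_is_hard_error_naming_site(self, tmp_path):
        toy = generate_toy_structure(1, [(1, "siteA", 5.0)])
        path = tmp_path / "toy.pdb"
        path.write_text(toy.pdb_text)
        with pytest.raises(StructureError, match="nickel"):
            load_structure(path, {"nickel": {"element": "NI"}})

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        pdb_text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C  \n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70  0.00           C  \n"
            "ATOM      3  CU   CU A 100      19.000   0.000   0.000  1.00  0.00          CU  \n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb_text)
        model = load_structure(path, {"cu": {"element": "CU"}})
        residue = model.atoms[model.atoms.res_id == 1]
        assert residue.array_length() == 1
        assert residue.coord[0, 0] == pytest.approx(9.0)

    def test_waters_dropped(self, tmp_path):
        pdb_text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
            "HETATM    2  O   HOH A 200       1.000   0.000   0.000  1.00  0.00           O  \n"
            "END\n"
        )
        path = tmp_path / "wat.pdb"
        path.write_text(pdb_text)
        model = load_structure(path)
        assert model.atoms.array_length() == 1


class TestSiteDistance:
    def test_three_four_five_triangle(self, tmp_path):
        model = toy_model(tmp_path, [(1, "siteA", 5.0)])
        assert site_distance(model, 1, "siteA") == pytest.approx(5.0, abs=1e-3)

    def test_coincident_atoms_give_zero(self, tmp_path):
        model = toy_model(tmp_path, [(1, "siteA", 0.0)])
        assert site_distance(model, 1, "siteA") == pytest.approx(0.0, abs=1e-3)

    def test_minimum_over_site_atoms(self):
        model = make_model(
            coords=[[0, 0, 0], [3, 4, 0], [0, 0, 12]],
            elements=["C", "CU", "CU"],
            res_ids=[1, 100, 101],
            hetero=[False, True, True],
            res_names=["ALA", "CU", "CU"],
            sites={"cu": [False, True, True]},
        )
        assert site_distance(model, 1, "cu") == pytest.approx(5.0, abs=1e-9)

    def test_symmetric_under_role_swap(self):
        model = make_model(
            coords=[[0, 0, 0], [1, 1, 1], [5, 5, 5], [6, 5, 5]],
            elements=["C", "C", "CU", "CU"],
            res_ids=[1, 1, 100, 100],
            hetero=[False, False, True, True],
            sites={"cu": [False, False, True, True]},
        )
        res_coords = model.atoms.coord[:2]
        site_coords = model.named_sites["cu"].coord
        forward = site_distance(model, 1, "cu")
        swapped = float(
            np.linalg.norm(
                site_coords[:, None, :] - res_coords[None, :, :], axis=-1
            ).min()
        )
        assert forward == pytest.approx(swapped, abs=1e-9)

    def test_invariant_to_rigid_body_motion(self, rng):
        coords = rng.normal(size=(5, 3)) * 5
        model = make_model(
            coords=coords,
            elements=["C", "C", "C", "CU", "CU"],
            res_ids=[1, 1, 2, 100, 100],
            hetero=[False, False, False, True, True],
            sites={"cu": [False, False, False, True, True]},
        )
        d0 = site_distance(model, 1, "cu")
        # random rotation (QR of a Gaussian matrix) plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = (coords.astype(np.float64) @ q.T + np.array([10.0, -3.0, 7.0]))
        model2 = make_model(
            coords=moved,
            elements=["C", "C", "C", "CU", "CU"],
            res_ids=[1, 1, 2, 100, 100],
            hetero=[False, False, False, True, True],
            sites={"cu": [False, False, False, True, True]},
        )
        assert site_distance(model2, 1, "cu") == pytest.approx(d0, abs=1e-5)

    def test_missing_residue_and_site_errors(self, tmp_path):
        model = toy_model(tmp_path, [(1, "siteA", 5.0)])
        with pytest.raises(StructureError, match="99"):
            site_distance(model, 99, "siteA")
        with pytest.raises(StructureError, match="other"):
            site_distance(model, 1, "other")


class TestCopperClassification:
    def test_isolated_copper_is_t1_cluster_is_t2t3(self):
        # three coppers within ~4 A of each other, one 13 A away
        model = make_model(
            coords=[[0, 0, 0], [13, 0, 0], [13, 4, 0], [13, 2, 3], [0, 0, 5]],
            elements=["CU", "CU", "CU", "CU", "C"],
            res_ids=[100, 101, 102, 103, 1],
            hetero=[True, True, True, True, False],
            res_names=["CU", "CU", "CU", "CU", "ALA"],
        )
        sites = classify_copper_sites(model)
        assert sites["T1Cu"].array_length() == 1
        assert sites["T1Cu"].res_id[0] == 100
        assert set(sites["T2/T3"].res_id) == {101, 102, 103}
        assert site_distance(model, 1, "T1Cu") == pytest.approx(5.0, abs=1e-6)

    def test_too_few_coppers_is_error(self):
        model = make_model(
            coords=[[0, 0, 0]], elements=["CU"], res_ids=[100], hetero=[True]
        )
        with pytest.raises(StructureError, match="copper"):
            classify_copper_sites(model)


class TestBurial:
    def test_isolated_residue_is_fully_accessible_surface(self):
        model = make_model(
            coords=[[0, 0, 0]], elements=["C"], res_ids=[1], hetero=[False],
            res_names=["ALA"],
        )
        rsa = relative_accessibility(model, 1, point_number=2000)
        r = vdw_radius_single("C") + 1.4
        expected = 4 * math.pi * r**2 / 129.0  # ALA reference max ASA
        assert rsa == pytest.approx(expected, rel=0.02)
        assert burial_class(rsa) == "surface"

    def _shell_model(self, radius, n_shell=120):
        # Fibonacci sphere of occluding carbon "residues" around a target atom
        idx = np.arange(n_shell) + 0.5
        phi = np.arccos(1 - 2 * idx / n_shell)
        theta = math.pi * (1 + 5**0.5) * idx
        shell = radius * np.stack(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
            axis=1,
        )
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        n = len(coords)
        return make_model(
            coords=coords,
            elements=["C"] * n,
            res_ids=list(range(1, n + 1)),
            hetero=[False] * n,
            res_names=["ALA"] + ["GLY"] * (n - 1),
        )

    def test_densely_enclosed_residue_is_buried(self):
        model = self._shell_model(radius=4.0)
        rsa = relative_accessibility(model, 1, point_number=500)
        assert rsa == pytest.approx(0.0, abs=0.01)
        assert burial_class(rsa) == "buried"

    def test_sasa_decreases_as_occluders_are_added(self):
        rsas = []
        for n_shell in (4, 12, 40):
            model = self._shell_model(radius=5.0, n_shell=n_shell)
            rsas.append(relative_accessibility(model, 1, point_number=500))
        assert rsas[0] > rsas[1] > rsas[2]

    def test_burial_class_thresholds(self):
        assert burial_class(0.05) == "buried"
        assert burial_class(0.20) == "partially buried"
        assert burial_class(0.50) == "surface"
        assert burial_class(None) == "unknown"

    def test_unknown_residue_type_is_unknown_class(self):
        model = make_model(
            coords=[[0, 0, 0]], elements=["C"], res_ids=[1], hetero=[False],
            res_names=["LIG"],
        )
        assert relative_accessibility(model, 1) is None


def test_annotation_table_mirrors_candidate_context(tmp_path):
    toy = generate_toy_structure(
        1, [(1, "T1Cu", 11.4), (1, "T2/T3", 5.3)], seed=1
    )
    path = tmp_path / "toy.pdb"
    path.write_text(toy.pdb_text)
    model = load_structure(path, toy.site_spec)
    ann = annotate_position(model, 1, point_number=200)
    assert ann.distances["T1Cu"] == pytest.approx(11.4, abs=1e-3)
    assert ann.distances["T2/T3"] == pytest.approx(5.3, abs=1e-3)
    assert ann.burial_class == "surface"
    out = tmp_path / "annot.tsv"
    write_annotation_table([ann], out)
    lines = out.read_text().splitlines()
    assert lines[0].split("\t")[:3] == ["position", "dist_T1Cu", "dist_T2/T3"]
    assert lines[1].startswith("1\t11.4\t5.3")
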
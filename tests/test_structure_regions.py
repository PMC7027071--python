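"""Structure reading, SASA and interface/surface/interior classification."""

import math

import numpy as np
import pytest

from conscluster.structure import (
    Atom,
    ComplexStructure,
    RegionLabel,
    Residue,
    classify_regions,
    compute_sasa,
    read_pdb,
    shrake_rupley,
)
from conscluster.synthetic import classify_coarse, coarse_settings

from _oracles import brute_force_sasa


def _coarse_table():
    return coarse_settings().radius_table


class TestReadPdb:
    def test_parses_ca_only_fixture(self, pdb_three_res):
        cx = read_pdb(pdb_three_res, protein_chains={"A"}, rna_chains={"R"})
        prot = cx.protein_residues
        assert len(prot) == 3
        assert [r.aa_type for r in prot] == ["GLY", "ALA", "SER"]
        assert all(r.ca_coord is not None for r in prot)
        np.testing.assert_allclose(prot[1].ca_coord, [3.8, 0.0, 0.0])
        assert len(cx.rna_residues) == 1

    def test_altloc_resolves_to_highest_occupancy(self, pdb_altloc):
        cx = read_pdb(pdb_altloc, protein_chains={"A"}, rna_chains=set())
        res = cx.protein_residues[0]
        cb = [a for a in res.atoms if a.name == "CB"]
        assert len(cb) == 1
        assert cb[0].coord[0] == pytest.approx(1.0)  # conformer A, occ 0.60

    def test_missing_chain_named_in_error(self, pdb_three_res):
        with pytest.raises(ValueError, match="Z"):
            read_pdb(pdb_three_res, protein_chains={"A", "Z"}, rna_chains={"R"})

    def test_roundtrip_of_generated_pdb(self, tmp_path, clustered_complex):
        syn = clustered_complex
        p = tmp_path / "syn.pdb"
        p.write_text(syn.pdb_text)
        cx = read_pdb(p, protein_chains={"A"}, rna_chains={"R"},
                      radius_table=_coarse_table())
        assert len(cx.protein_residues) == len(syn.sequence)
        orig = {r.id: r.ca_coord for r in syn.structure.protein_residues}
        for r in cx.protein_residues:
            np.testing.assert_allclose(r.ca_coord, orig[r.id], atol=5e-4)


class TestSasa:
    def test_isolated_atom_equals_sphere_area(self):
        # a lone carbon: SASA is the full expanded sphere, 4*pi*(1.87+1.4)^2
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.87]))
        expected = 4 * math.pi * 3.27**2
        assert area[0] == pytest.approx(expected, rel=0.005)

    def test_occlusion_never_increases_area(self):
        # coincident atoms: each at most a lone-atom area, total at most 2x
        single = shrake_rupley(np.zeros((1, 3)), np.array([1.87]))[0]
        pair = shrake_rupley(np.zeros((2, 3)), np.array([1.87, 1.87]))
        assert np.all(pair <= single + 1e-9)
        assert pair.sum() <= 2 * single + 1e-9

    def test_adding_atoms_is_monotone(self, rng):
        coords = rng.uniform(0, 12, size=(12, 3))
        radii = np.full(12, 1.7)
        base = shrake_rupley(coords[:8], radii[:8])
        grown = shrake_rupley(coords, radii)
        assert np.all(grown[:8] <= base + 1e-9)

    @staticmethod
    def packed_fixture(n, box, seed, min_sep=3.0):
        rng = np.random.default_rng(seed)
        pts = []
        while len(pts) < n:
            p = rng.uniform(0, box, 3)
            if not pts or np.min(np.linalg.norm(np.array(pts) - p, axis=1)) >= min_sep:
                pts.append(p)
        return np.array(pts), rng.uniform(1.4, 1.9, size=n)

    @pytest.mark.parametrize("fixture", ["linear", "packed"])
    def test_matches_dense_brute_force_oracle(self, fixture):
        if fixture == "linear":
            coords = np.column_stack([np.arange(5) * 2.5, np.zeros(5), np.zeros(5)])
            radii = np.random.default_rng(0).uniform(1.4, 1.9, size=5)
        else:
            coords, radii = self.packed_fixture(20, 14.0, seed=1)
        mine = shrake_rupley(coords, radii, n_points=960)
        oracle = brute_force_sasa(coords, radii, n_points=10000)
        np.testing.assert_allclose(mine, oracle, rtol=0.02)

    def test_residue_sasa_sums_atoms(self, pdb_three_res):
        cx = read_pdb(pdb_three_res, protein_chains={"A"}, rna_chains={"R"})
        per_res = compute_sasa(cx)
        assert all(v > 0 for v in per_res.values())


def _toy_complex(protein_xyz, rna_xyz, aa="ALA"):
    residues = []
    for i, xyz in enumerate(protein_xyz, 1):
        residues.append(Residue("A", i, "", aa, [
            Atom("CA", "C", np.asarray(xyz, float), 3.0)]))
    for j, xyz in enumerate(rna_xyz, 1):
        residues.append(Residue("R", j, "", "U", [
            Atom("P", "P", np.asarray(xyz, float), 3.0)]))
    return ComplexStructure(residues, frozenset({"A"}), frozenset({"R"}))


class TestClassifyRegions:
    REF = {"ALA": 4 * math.pi * 4.4**2}

    def test_contact_residue_is_interface(self):
        # protein residue 5 Å from an RNA atom loses far more than 0.1 Å²
        cx = _toy_complex([[0, 0, 0]], [[5.0, 0, 0]])
        table = classify_regions(cx, reference_table=self.REF)
        assert table.labels[("A", 1, "")] is RegionLabel.INTERFACE
        assert table.records[("A", 1, "")].delta_sasa > 0.1

    def test_far_exposed_residue_is_surface(self):
        cx = _toy_complex([[0, 0, 0]], [[50.0, 0, 0]])
        table = classify_regions(cx, reference_table=self.REF)
        assert table.labels[("A", 1, "")] is RegionLabel.SURFACE

    def test_buried_untouched_residue_is_interior(self):
        # center residue caged by 14 neighbours, RNA far away
        shell = []
        for u in np.linspace(0, math.pi, 4)[1:-1]:
            for v in np.linspace(0, 2 * math.pi, 7)[:-1]:
                shell.append([4.2 * math.sin(u) * math.cos(v),
                              4.2 * math.sin(u) * math.sin(v),
                              4.2 * math.cos(u)])
        shell += [[0, 0, 4.2], [0, 0, -4.2]]
        cx = _toy_complex([[0, 0, 0]] + shell, [[80.0, 0, 0]])
        table = classify_regions(cx, reference_table=self.REF)
        rec = table.records[("A", 1, "")]
        assert rec.delta_sasa == pytest.approx(0.0, abs=1e-9)
        assert table.labels[("A", 1, "")] is RegionLabel.INTERIOR

    def test_unknown_residue_type_raises(self):
        cx = _toy_complex([[0, 0, 0]], [[5.0, 0, 0]], aa="GLY")
        with pytest.raises(KeyError, match="GLY"):
            classify_regions(cx, reference_table=self.REF)

    def test_labels_partition_protein_residues(self, clustered_complex):
        table = clustered_complex.region_table
        n = len(clustered_complex.structure.protein_residues)
        counts = {lab: len(table.ids_with_label(lab)) for lab in RegionLabel}
        assert sum(counts.values()) == n
        assert len(table.labels) == n

    def test_no_rna_means_no_interface(self, clustered_complex):
        # reclassify with RNA removed: zero interface residues
        syn = clustered_complex
        protein = syn.structure.without_chains(syn.structure.rna_chain_ids)
        merged = ComplexStructure(
            residues=protein.residues,
            protein_chain_ids=protein.protein_chain_ids,
            rna_chain_ids=frozenset({"R"}),  # declared but empty
        )
        table = classify_coarse(merged, syn.coarse)
        assert table.interface_ids == []

    def test_synthetic_ground_truth_recovered_exactly(self, tmp_path, clustered_complex):
        # end-to-end: written PDB -> parse -> classify == generator truth
        syn = clustered_complex
        p = tmp_path / "syn.pdb"
        p.write_text(syn.pdb_text)
        cx = read_pdb(p, protein_chains={"A"}, rna_chains={"R"},
                      radius_table=_coarse_table())
        table = classify_coarse(cx, syn.coarse)
        assert set(table.interface_ids) == syn.true_interface
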
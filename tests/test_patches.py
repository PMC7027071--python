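"""Surface patches, solvent vectors and interface ranking."""

import math

import numpy as np
import pytest
from scipy import stats

from conscluster.clustering import ResidueSet
from conscluster.patches import (
    generate_patch,
    patch_rho,
    rank_interface,
    sample_patches,
    solvent_vectors,
    surface_residue_set,
)


def rs(coords):
    coords = np.asarray(coords, float)
    return ResidueSet(ids=[("A", i, "") for i in range(len(coords))], coords=coords)


def ring_with_apex(apex_height=5.0, n_ring=10, radius=6.0):
    ring = [[radius * math.cos(2 * math.pi * k / n_ring),
             radius * math.sin(2 * math.pi * k / n_ring), 0.0]
            for k in range(n_ring)]
    return rs([[0.0, 0.0, apex_height]] + ring)


class TestSolventVectors:
    def test_apex_above_ring_points_along_normal(self):
        surface = ring_with_apex()
        v = solvent_vectors(surface, k=10)[("A", 0, "")]
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-9)

    def test_unit_norm(self, rng):
        surface = rs(rng.uniform(0, 30, size=(25, 3)))
        for v in solvent_vectors(surface).values():
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_centroid_raises(self):
        surface = ring_with_apex(apex_height=0.0)  # apex at ring centroid
        with pytest.raises(ValueError, match="degenerate"):
            solvent_vectors(surface, k=10)

    def test_neighbour_selection_matches_brute_force(self, rng):
        coords = rng.uniform(0, 40, size=(30, 3))
        surface = rs(coords)
        vecs = solvent_vectors(surface, k=10)
        for i in range(5):
            d = np.linalg.norm(coords - coords[i], axis=1)
            nearest = np.argsort(d, kind="stable")[1:11]
            centroid = coords[nearest].mean(axis=0)
            expected = coords[i] - centroid
            expected /= np.linalg.norm(expected)
            np.testing.assert_allclose(vecs[("A", i, "")], expected, atol=1e-9)


class TestGeneratePatch:
    def test_vanishing_radius_keeps_only_center(self, rng):
        surface = rs(rng.uniform(0, 30, size=(15, 3)))
        patch = generate_patch(surface, surface.ids[3], method=1, radius=1e-9)
        assert patch.members == [surface.ids[3]]

    def test_planar_toy_distance_rule(self):
        # center + 5 residues at 10 Å + 2 at 25 Å: method-1 patch has 6 members
        near = [[10 * math.cos(a), 10 * math.sin(a), 0] for a in np.linspace(0, 3, 5)]
        far = [[25, 0, 0], [0, 25, 0]]
        surface = rs([[0, 0, 0]] + near + far)
        patch = generate_patch(surface, surface.ids[0], method=1, radius=20.0)
        assert len(patch.members) == 6

    def test_method3_excludes_antipode(self):
        # residues on a sphere: the far pole's solvent vector is antiparallel
        pts = []
        golden = math.pi * (1 + math.sqrt(5))
        for i in range(40):
            z = 1 - 2 * (i + 0.5) / 40
            r = math.sqrt(1 - z * z)
            pts.append([15 * r * math.cos(golden * i), 15 * r * math.sin(golden * i),
                        15 * z])
        surface = rs(pts)
        center = surface.ids[0]
        big = 40.0  # radius large enough to reach the antipode
        m2 = generate_patch(surface, center, method=2, radius=big)
        m3 = generate_patch(surface, center, method=3, radius=big)
        assert set(m3.members) < set(m2.members)
        vecs = solvent_vectors(surface)
        vc = vecs[center]
        for rid in m3.members:
            angle = math.degrees(math.acos(np.clip(np.dot(vecs[rid], vc), -1, 1)))
            assert angle < 110.0

    def test_method3_members_subset_of_method2(self, rng):
        surface = rs(rng.uniform(0, 40, size=(60, 3)))
        vecs = solvent_vectors(surface)
        for i in range(0, 60, 7):
            m2 = generate_patch(surface, surface.ids[i], 2, radius=18.0)
            m3 = generate_patch(surface, surface.ids[i], 3, radius=18.0, vectors=vecs)
            assert set(m3.members) <= set(m2.members)

    def test_non_surface_center_raises(self, rng):
        surface = rs(rng.uniform(0, 30, size=(12, 3)))
        with pytest.raises(ValueError, match="center"):
            generate_patch(surface, ("B", 1, ""), 1, radius=20.0)


class TestSamplePatches:
    def test_deterministic_under_seed(self, rng):
        surface = rs(rng.uniform(0, 30, size=(40, 3)))
        a = sample_patches(surface, 1, n=50, rng=123)
        b = sample_patches(surface, 1, n=50, rng=123)
        assert [p.center for p in a] == [p.center for p in b]

    def test_centers_are_surface_residues(self, rng):
        surface = rs(rng.uniform(0, 30, size=(40, 3)))
        out = sample_patches(surface, 1, n=200, rng=1)
        assert len(out) == 200
        assert all(p.center in surface.ids for p in out)

    def test_center_frequencies_uniform(self, rng):
        surface = rs(rng.uniform(0, 30, size=(20, 3)))
        out = sample_patches(surface, 1, n=100_000, rng=9, radius=1e-9)
        counts = np.zeros(20)
        index = {rid: i for i, rid in enumerate(surface.ids)}
        for p in out:
            counts[index[p.center]] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestRankInterface:
    def test_interface_above_all_patches_ranks_first(self, rng):
        rhos = rng.uniform(0.5, 1.4, size=1000)
        rk = rank_interface(1.5, rhos)
        assert rk.rank == 1 and rk.decile == 1

    def test_interface_at_patch_mean_gives_zero_z(self, rng):
        rhos = np.concatenate([np.full(500, 0.8), np.full(500, 1.2)])
        rk = rank_interface(1.0, rhos)
        assert rk.z == pytest.approx(0.0)

    def test_z_formula_arithmetic(self):
        rhos = np.full(100, 1.0)
        rhos[:50] += 0.1
        rhos[50:] -= 0.1  # mean 1.0, sigma 0.1
        rk = rank_interface(1.2, rhos)
        assert rk.z == pytest.approx(-20.0)

    def test_sigma_zero_gives_nan_z_but_a_decile(self):
        rk = rank_interface(1.2, np.full(100, 1.0))
        assert math.isnan(rk.z)
        assert rk.rank == 1 and rk.decile == 1

    def test_percentile_significance_flag(self, rng):
        rhos = rng.normal(1.0, 0.1, size=1000)
        hi = rank_interface(float(np.percentile(rhos, 99)) + 1e-6, rhos)
        lo = rank_interface(float(np.percentile(rhos, 50)), rhos)
        assert hi.significant_percentile and hi.significant_z
        assert not lo.significant_percentile

    def test_decile_spans_one_to_ten(self, rng):
        rhos = np.sort(rng.uniform(0, 2, size=999))
        assert rank_interface(2.5, rhos).decile == 1
        assert rank_interface(-1.0, rhos).decile == 10


class TestPatchRho:
    def test_fewer_than_two_conserved_gives_zero_by_default(self, rng):
        surface = rs(rng.uniform(0, 30, size=(20, 3)))
        patch = generate_patch(surface, surface.ids[0], 1, radius=50.0)
        entropies = {rid: 1.0 for rid in surface.ids}  # no one below the mean
        assert patch_rho(patch, surface, entropies) == 0.0

    def test_patch_mean_criterion_selects_low_entropy(self, rng):
        surface = rs(rng.uniform(0, 30, size=(20, 3)))
        patch = generate_patch(surface, surface.ids[0], 1, radius=50.0)
        entropies = {rid: (0.0 if i < 8 else 2.5)
                     for i, rid in enumerate(surface.ids)}
        rho = patch_rho(patch, surface, entropies)
        assert math.isfinite(rho) and rho > 0


def test_surface_residue_set_on_synthetic_complex(clustered_complex):
    syn = clustered_complex
    surface = surface_residue_set(
        syn.structure, reference_table=syn.coarse.reference_table,
        probe_radius=syn.coarse.probe_radius, n_points=syn.coarse.n_points)
    # free-protein surface must cover the (RNA-contacting) interface shell
    assert len(surface) > 0
    assert syn.true_interface <= set(surface.ids) | set(
        syn.region_table.interior_ids)
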
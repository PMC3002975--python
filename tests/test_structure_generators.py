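"""Lattice clusters, packings, and their contact networks."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from packnet.graph_stats import compute_degrees, edge_degree_correlation
from packnet.spatial_network import (build_contact_graph, compute_rdf,
                                     first_shell_cutoff)
from packnet.structure_generators import (LatticeSpec,
                                          connect_first_neighbors,
                                          generate_hard_sphere_packing,
                                          generate_lattice_cluster,
                                          generate_polymer_melt_proxy)


def motif(lattice, n):
    return generate_lattice_cluster(
        LatticeSpec(lattice_type=lattice, n_sites=n))


class TestLatticeClusters:
    @pytest.mark.parametrize("lattice,n_shell", [
        ("HCP", 12), ("FCC", 12), ("BCC", 8), ("SC", 6),
    ])
    def test_center_plus_first_shell(self, lattice, n_shell):
        coords = motif(lattice, n_shell + 1)
        d = np.linalg.norm(coords.positions - coords.positions[0], axis=1)
        # site 0 is the central site; the full first shell sits at spacing
        np.testing.assert_allclose(np.sort(d)[1:], 1.0, rtol=1e-9)

    @pytest.mark.parametrize("lattice,coordination", [
        ("HCP", 12), ("FCC", 12), ("BCC", 8), ("SC", 6),
    ])
    def test_interior_coordination(self, lattice, coordination):
        g = connect_first_neighbors(motif(lattice, 400), spacing=1.0)
        k = compute_degrees(g)
        assert k.max() == coordination
        # the bulk of a 400-site cluster contains full-shell nodes
        assert (k == coordination).sum() > 50

    def test_motif_shell_degrees(self):
        g = connect_first_neighbors(motif("HCP", 13), spacing=1.0)
        k = compute_degrees(g)
        assert k.max() == 12
        assert np.sort(k)[:-1].min() >= 4

    def test_bcc_and_sc_motifs(self):
        for lattice, deg, n in (("BCC", 8, 9), ("SC", 6, 7)):
            g = connect_first_neighbors(motif(lattice, n), spacing=1.0)
            assert compute_degrees(g).max() == deg

    def test_compactness_no_interior_vacancy(self):
        """Every lattice site strictly closer to the center than the
        farthest selected site is itself selected (radial fill)."""
        from packnet.structure_generators import _enumerate_sites
        coords = motif("FCC", 150)
        center = coords.positions[0]
        d = np.linalg.norm(coords.positions - center, axis=1)
        r_far = d.max()
        all_sites = _enumerate_sites("FCC", 1.0, r_far + 2.0)
        inner = all_sites[np.linalg.norm(all_sites, axis=1) < r_far - 1e-9]
        sel = {tuple(np.round(p - center, 6)) for p in coords.positions}
        missing = [p for p in inner if tuple(np.round(p, 6)) not in sel]
        assert not missing

    def test_determinism(self):
        spec = LatticeSpec(lattice_type="HCP", n_sites=137,
                           jitter_sigma=0.05, seed=9)
        a = generate_lattice_cluster(spec)
        b = generate_lattice_cluster(spec)
        assert np.array_equal(a.positions, b.positions)

    def test_exact_site_count(self):
        for n in (1, 2, 13, 100, 500):
            assert motif("HCP", n).n_points == n

    def test_hex_plate_fill(self):
        spec = LatticeSpec(lattice_type="HCP", n_sites=500,
                           fill_rule="hex_plate")
        coords = generate_lattice_cluster(spec)
        assert coords.n_points == 500
        zs = np.unique(np.round(coords.positions[:, 2], 6))
        gaps = np.diff(zs)
        np.testing.assert_allclose(gaps, np.sqrt(8 / 3) / 2, rtol=1e-6)

    def test_hex_plate_requires_hcp(self):
        with pytest.raises(ValueError):
            LatticeSpec(lattice_type="FCC", n_sites=100,
                        fill_rule="hex_plate")

    def test_jitter_changes_coordinates_but_not_count(self):
        base = generate_lattice_cluster(
            LatticeSpec(lattice_type="SC", n_sites=50))
        jit = generate_lattice_cluster(
            LatticeSpec(lattice_type="SC", n_sites=50,
                        jitter_sigma=0.02, seed=1))
        assert jit.n_points == 50
        assert not np.array_equal(base.positions, jit.positions)
        assert np.abs(jit.positions - base.positions).max() < 0.2

    def test_max_degree_bounded_by_twelve(self):
        for lattice in ("HCP", "FCC", "BCC", "SC"):
            g = connect_first_neighbors(motif(lattice, 250), spacing=1.0)
            assert compute_degrees(g).max() <= 12


class TestHardSpherePacking:
    def test_single_point(self):
        cs = generate_hard_sphere_packing(1, 1.0, 5.0, seed=0)
        assert cs.n_points == 1
        assert np.linalg.norm(cs.positions[0]) <= 5.0

    def test_minimum_distance_respected(self):
        cs = generate_hard_sphere_packing(150, 1.0, 4.0, seed=3)
        assert pdist(cs.positions).min() >= 1.0

    def test_reproducible_by_seed(self):
        a = generate_hard_sphere_packing(60, 1.0, 4.0, seed=5)
        b = generate_hard_sphere_packing(60, 1.0, 4.0, seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_infeasible_packing_reports_count(self):
        with pytest.raises(RuntimeError, match="packing infeasible"):
            generate_hard_sphere_packing(100, 1.0, 1.5, seed=0,
                                         max_attempts_per_point=200)

    def test_dense_packing_network_is_assortative(self):
        cs = generate_hard_sphere_packing(300, 1.0, 5.0, seed=12)
        rdf = compute_rdf(cs, bin_width=0.05, r_max=4.0)
        r_c = first_shell_cutoff(rdf)
        g = build_contact_graph(cs, r_c)
        assert edge_degree_correlation(g) > 0


class TestPolymerMeltProxy:
    def test_bead_count_and_chain_metadata(self):
        cs = generate_polymer_melt_proxy(n_chains=4, chain_length=8,
                                         bond_length=1.0, min_dist=1.0,
                                         container_radius=6.0, seed=2)
        assert cs.n_points == 32
        assert len(set(cs.chain_ids)) == 4
        for c in set(cs.chain_ids):
            seq = [s for cid, s in zip(cs.chain_ids, cs.sequence_index)
                   if cid == c]
            assert seq == list(range(8))

    def test_chain_edges_present_below_cutoff(self):
        cs = generate_polymer_melt_proxy(n_chains=1, chain_length=5,
                                         bond_length=1.0, min_dist=1.0,
                                         container_radius=5.0, seed=0)
        g = build_contact_graph(cs, r_c=0.5, chain_edges=True)
        assert g.n_edges == 4  # the 4 backbone bonds alone

    def test_bond_lengths_exact(self):
        cs = generate_polymer_melt_proxy(n_chains=2, chain_length=6,
                                         bond_length=0.9, min_dist=0.8,
                                         container_radius=5.0, seed=4)
        pos = cs.positions
        for c in ("c0", "c1"):
            idx = [i for i, cid in enumerate(cs.chain_ids) if cid == c]
            bonds = np.linalg.norm(np.diff(pos[idx], axis=0), axis=1)
            np.testing.assert_allclose(bonds, 0.9, rtol=1e-9)

    def test_dense_melt_rdf_first_peak_near_min_dist(self):
        cs = generate_polymer_melt_proxy(n_chains=10, chain_length=10,
                                         bond_length=1.0, min_dist=1.0,
                                         container_radius=4.0, seed=8)
        rdf = compute_rdf(cs, bin_width=0.1, r_max=3.5)
        peak = rdf.bin_centers[np.argmax(rdf.g)]
        assert 0.9 < peak < 1.5
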
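"""Coordinates -> RDF -> cutoff -> contact graph, plus residue nodes."""

import math

import numpy as np
import pytest

from packnet.graph_stats import compute_degrees
from packnet.io import read_pdb
from packnet.spatial_network import (CoordinateSet, RadialDistribution,
                                     build_contact_graph, compute_rdf,
                                     first_shell_cutoff, residue_nodes)
from packnet.structure_generators import (LatticeSpec,
                                          connect_first_neighbors,
                                          generate_lattice_cluster)


def line_coords(n, spacing, **kw):
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return CoordinateSet(positions=pos, **kw)


class TestCoordinateSet:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            CoordinateSet(positions=np.array([[0, 0, np.inf]]))

    def test_rejects_nonincreasing_sequence(self):
        with pytest.raises(ValueError):
            CoordinateSet(positions=np.zeros((2, 3)),
                          chain_ids=("a", "a"), sequence_index=(2, 1))

    def test_minimum_image_distances(self):
        cs = CoordinateSet(positions=np.array([[0.5, 0, 0], [9.5, 0, 0]]),
                           box=(10.0, 10.0, 10.0))
        assert cs.pairwise_distances()[0] == pytest.approx(1.0)


class TestRDF:
    def test_two_points_single_bin(self):
        cs = CoordinateSet(positions=np.array([[0, 0, 0], [1.23, 0, 0]]))
        rdf = compute_rdf(cs, bin_width=0.1, r_max=3.0)
        occupied = np.nonzero(rdf.g)[0]
        assert len(occupied) == 1
        lo, hi = rdf.bin_edges[occupied[0]], rdf.bin_edges[occupied[0] + 1]
        assert lo <= 1.23 < hi

    def test_uniform_periodic_gas_flat_at_large_r(self):
        rng = np.random.default_rng(42)
        cs = CoordinateSet(positions=rng.uniform(0, 20, size=(4000, 3)),
                           box=(20.0, 20.0, 20.0))
        rdf = compute_rdf(cs, bin_width=0.25, r_max=8.0)
        far = rdf.g[rdf.bin_centers > 4.0]
        assert abs(far.mean() - 1.0) < 0.02
        assert np.all(np.abs(far - 1.0) < 0.15)

    def test_hcp_first_peak_at_unit_spacing(self):
        coords = generate_lattice_cluster(
            LatticeSpec(lattice_type="HCP", n_sites=200))
        rdf = compute_rdf(coords, bin_width=0.05, r_max=3.0)
        first = np.nonzero(rdf.g)[0][0]
        c = rdf.bin_centers[first]
        assert abs(c - 1.0) < 0.05

    def test_rmax_beyond_half_box_rejected(self):
        cs = CoordinateSet(positions=np.random.default_rng(0).uniform(
            0, 5, size=(10, 3)), box=(5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            compute_rdf(cs, bin_width=0.1, r_max=4.0)


class TestFirstShellCutoff:
    def test_constructed_peak_and_minimum(self):
        edges = np.arange(0.0, 2.05, 0.1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        g = np.exp(-((centers - 1.0) / 0.1) ** 2) * 3.0 \
            + np.exp(-((centers - 1.8) / 0.1) ** 2) * 2.0
        rdf = RadialDistribution(bin_edges=edges, g=g, density=1.0)
        r_c = first_shell_cutoff(rdf, smooth_bins=1)
        assert 1.2 < r_c < 1.6

    def test_monotone_rdf_fails(self):
        edges = np.arange(0.0, 1.05, 0.1)
        rdf = RadialDistribution(bin_edges=edges,
                                 g=np.linspace(0, 1, len(edges) - 1),
                                 density=1.0)
        with pytest.raises(ValueError):
            first_shell_cutoff(rdf)

    def test_hcp_cutoff_between_first_and_second_shell(self):
        coords = generate_lattice_cluster(
            LatticeSpec(lattice_type="HCP", n_sites=300))
        rdf = compute_rdf(coords, bin_width=0.05, r_max=3.0)
        r_c = first_shell_cutoff(rdf)
        assert 1.0 < r_c < math.sqrt(2.0)
        # any cutoff in that window reproduces the first-neighbor network
        g1 = build_contact_graph(coords, r_c)
        g2 = connect_first_neighbors(coords, spacing=1.0)
        assert g1.edges == g2.edges


class TestBuildContactGraph:
    def test_collinear_points_path_graph(self):
        cs = line_coords(3, 1.0)
        g = build_contact_graph(cs, r_c=1.5)
        assert sorted(compute_degrees(g)) == [1, 1, 2]

    def test_chain_edges_alone(self):
        cs = line_coords(3, 1.0, chain_ids=("a",) * 3,
                         sequence_index=(0, 1, 2))
        g = build_contact_graph(cs, r_c=0.5, chain_edges=True)
        assert g.edges == frozenset({(0, 1), (1, 2)})

    def test_strict_inequality_at_cutoff(self):
        cs = line_coords(2, 1.0)
        assert build_contact_graph(cs, r_c=1.0).n_edges == 0
        assert build_contact_graph(cs, r_c=1.0 + 1e-9).n_edges == 1

    def test_hcp_motif_center_degree_12(self):
        coords = generate_lattice_cluster(
            LatticeSpec(lattice_type="HCP", n_sites=13))
        g = build_contact_graph(coords, r_c=1.0 + 1e-6)
        assert max(compute_degrees(g)) == 12

    def test_edge_set_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        cs = CoordinateSet(positions=rng.uniform(0, 3, size=(40, 3)))
        prev = frozenset()
        for r_c in (0.5, 1.0, 1.5, 2.5):
            edges = build_contact_graph(cs, r_c).edges
            assert prev <= edges
            prev = edges

    def test_periodic_adjacency_matches_replicated_oracle(self):
        """Minimum-image adjacency of a periodic cell equals adjacency on
        explicit 27-cell replication, restricted to in-cell pairs."""
        rng = np.random.default_rng(11)
        box = 4.0
        pos = rng.uniform(0, box, size=(25, 3))
        cs = CoordinateSet(positions=pos, box=(box,) * 3)
        r_c = 1.3
        g = build_contact_graph(cs, r_c)
        expected = set()
        shifts = [np.array([i, j, k]) * box
                  for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        for i in range(25):
            for j in range(i + 1, 25):
                if any(np.linalg.norm(pos[i] - (pos[j] + s)) < r_c
                       for s in shifts):
                    expected.add((i, j))
        assert set(g.edges) == expected


PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  C   ALA A   1       2.000  -1.400   0.000  1.00  0.00           C
ATOM      5  N   GLY A   2       3.300  -1.500   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.100  -2.700   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.500  -2.300   0.300  1.00  0.00           C
ATOM      8  N   SER A   3       6.400  -3.300   0.300  1.00  0.00           N
ATOM      9  CA  SER A   3       7.800  -3.100   0.600  1.00  0.00           C
ATOM     10  CB  SER A   3       8.600  -4.400   0.600  1.00  0.00           C
HETATM   11  O   HOH A   4      10.000  10.000  10.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB ASER A   1       1.500   0.000   0.000  0.50  0.00           C
ATOM      3  CB BSER A   1       1.600   0.100   0.000  0.50  0.00           C
END
"""


class TestResidueNodes:
    def test_three_residue_fixture(self, tmp_path):
        p = tmp_path / "tri.pdb"
        p.write_text(PDB_3RES)
        coords = residue_nodes(read_pdb(p))
        assert coords.n_points == 3  # the water is excluded
        # glycine node sits at its CA
        np.testing.assert_allclose(coords.positions[1], [4.1, -2.7, 0.0])
        # ALA and SER nodes sit at CB
        np.testing.assert_allclose(coords.positions[0], [2.0, 1.4, 0.0])

    def test_altloc_gives_single_node(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        coords = residue_nodes(read_pdb(p))
        assert coords.n_points == 1

    def test_ca_only_fallback(self, tmp_path):
        p = tmp_path / "ca.pdb"
        lines = []
        for i in range(10):
            lines.append(
                f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    "
                f"{i * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        p.write_text("\n".join(lines) + "\nEND\n")
        coords = residue_nodes(read_pdb(p))
        assert coords.n_points == 10
        # 3.8 A spacing with r_c = 6.7 A: interior nodes reach i±1 only
        g = build_contact_graph(coords, r_c=6.7)
        k = compute_degrees(g)
        assert list(k[1:-1]) == [2] * 8
        assert k[0] == k[-1] == 1
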
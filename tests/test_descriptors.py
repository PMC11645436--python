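import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import random_rotation, transform_structure
from ptmct import descriptors as dsc
from ptmct.io import ProteinStructure, Residue


def point_structure(coords, protein_id="pts"):
    """Structure with one single-CA residue per coordinate."""
    residues = [Residue(position=i + 1, name="GLY",
                        atoms={"CA": np.asarray(c, dtype=float)})
                for i, c in enumerate(coords)]
    return ProteinStructure(protein_id=protein_id, residues=residues)


class TestContactGraph:
    def test_two_residues_within_cutoff(self):
        s = point_structure([[0, 0, 0], [5, 0, 0]])
        cg = dsc.build_contact_graph(s, cutoff=8.0)
        assert cg.graph.number_of_edges() == 1

    def test_helix_backbone_adjacency(self, helix):
        cg = dsc.build_contact_graph(helix)
        for i in range(1, 30):
            assert cg.graph.has_edge(i, i + 1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 25, size=(40, 3))
        s = point_structure(coords)
        cg = dsc.build_contact_graph(s, cutoff=8.0)
        expected = {(i + 1, j + 1)
                    for i in range(40) for j in range(i + 1, 40)
                    if np.linalg.norm(coords[i] - coords[j]) <= 8.0}
        got = {tuple(sorted(e)) for e in cg.graph.edges}
        assert got == expected


class TestShortestPath:
    def test_adjacent_and_self(self, helix):
        cg = dsc.build_contact_graph(helix)
        assert dsc.shortest_path_distance(cg, 1, 2) == 1
        assert dsc.shortest_path_distance(cg, 7, 7) == 0

    def test_disconnected_sentinel(self):
        s = point_structure([[0, 0, 0], [100, 0, 0], [104, 0, 0]])
        cg = dsc.build_contact_graph(s, cutoff=8.0)
        assert dsc.shortest_path_distance(cg, 1, 2) == 4   # L + 1

    def test_unknown_node(self, helix):
        cg = dsc.build_contact_graph(helix)
        with pytest.raises(KeyError):
            dsc.shortest_path_distance(cg, 1, 999)

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 20, size=(25, 3))
        s = point_structure(coords)
        cg = dsc.build_contact_graph(s, cutoff=8.0)

        def bfs(src, dst):
            frontier, seen, depth = {src}, {src}, 0
            while frontier:
                if dst in frontier:
                    return depth
                frontier = {v for u in frontier
                            for v in cg.graph.neighbors(u)} - seen
                seen |= frontier
                depth += 1
            return 26
        for i, j in itertools.combinations(range(1, 26), 2):
            assert dsc.shortest_path_distance(cg, i, j) == bfs(i, j)


class TestCircularVariance:
    def test_single_neighbor_is_zero(self):
        s = point_structure([[0, 0, 0], [3, 0, 0]])
        assert dsc.circular_variance(s, 1) == pytest.approx(0.0)

    def test_opposed_neighbors_give_one(self):
        s = point_structure([[0, 0, 0], [4, 0, 0], [-4, 0, 0]])
        assert dsc.circular_variance(s, 1) == pytest.approx(1.0)

    def test_uniform_sphere_near_one(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((500, 3))
        pts = 5.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        s = point_structure(np.vstack([[0, 0, 0], pts]))
        assert abs(dsc.circular_variance(s, 1) - 1.0) < 0.1

    def test_no_neighbors_warns_and_returns_zero(self):
        s = point_structure([[0, 0, 0], [100, 0, 0]])
        with pytest.warns(UserWarning):
            assert dsc.circular_variance(s, 1) == 0.0


def brute_force_opd(points):
    """Independent OPD G0: explicit python loop over ordered quadruples."""
    points = np.asarray(points, dtype=float)
    total, count = 0.0, 0
    for quad in itertools.permutations(range(len(points)), 4):
        a, b, c, d = (points[q] for q in quad)

        def u(p, q):
            v = q - p
            return v / np.linalg.norm(v)
        g = np.dot(np.cross(u(a, b), u(c, d)), u(a, d)) \
            * np.dot(u(a, b), u(b, c)) * np.dot(u(b, c), u(c, d))
        total += g
        count += 1
    return total / count


class TestOPDChirality:
    def test_coplanar_is_zero(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(0, 10, (6, 2)), np.zeros(6)])
        assert dsc.opd_chirality_g0(pts) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_negates(self, helix):
        mirrored = transform_structure(helix, np.diag([1.0, 1.0, -1.0]),
                                       np.zeros(3))
        for n in (5, 10):
            a = dsc.opd_chirality_index(helix, 15, n)
            b = dsc.opd_chirality_index(mirrored, 15, n)
            assert a == pytest.approx(-b, rel=1e-9)
            assert abs(a) > 0

    def test_matches_quadruple_enumeration_oracle(self, helix):
        ca = helix.ca_coords()
        center = helix.residue_at(15).ca
        order = np.argsort(np.linalg.norm(ca - center, axis=1))
        pts = ca[order[:5]]
        assert dsc.opd_chirality_index(helix, 15, 5) == pytest.approx(
            brute_force_opd(pts), rel=1e-9)

    def test_handedness_sign_flips(self, helix):
        left = transform_structure(helix, np.diag([1.0, -1.0, 1.0]),
                                   np.zeros(3))
        r = dsc.opd_chirality_index(helix, 15, 5)
        l = dsc.opd_chirality_index(left, 15, 5)
        assert np.sign(r) == -np.sign(l) != 0

    def test_too_few_points(self):
        s = point_structure([[0, 0, 0], [3, 0, 0], [6, 0, 0]])
        with pytest.raises(ValueError):
            dsc.opd_chirality_index(s, 1, 5)


class TestPocketDescriptors:
    def test_isolated_residue_fully_exposed(self):
        s = point_structure([[0, 0, 0], [300, 0, 0]])
        asv, mir, pk = dsc.pocket_descriptors(s, 1)
        assert pk == pytest.approx(0.0, abs=0.02)
        assert mir == pytest.approx(1.0)    # minimum of the burial scale
        assert asv > 0

    def test_caged_residue_at_cap(self, cage):
        asv, mir, pk = dsc.pocket_descriptors(cage, 1)
        assert mir == pytest.approx(11.0)   # cap = r_max + 1

    def test_cage_more_buried_than_shell(self, cage):
        _, mir_center, _ = dsc.pocket_descriptors(cage, 1)
        _, mir_shell, _ = dsc.pocket_descriptors(cage, 50)
        assert mir_center > mir_shell

    def test_grid_convergence(self, helix):
        _, _, pk1 = dsc.pocket_descriptors(helix, 15, grid_spacing=1.0)
        _, _, pk2 = dsc.pocket_descriptors(helix, 15, grid_spacing=0.5)
        assert abs(pk1 - pk2) < 0.1


def oracle_w1_1d(mu_x, mu_y, support_x, support_y):
    """W1 on the line equals the integral of |CDF difference|."""
    grid = np.unique(np.concatenate([support_x, support_y]))
    cdf_x = np.array([mu_x[support_x <= g].sum() for g in grid])
    cdf_y = np.array([mu_y[support_y <= g].sum() for g in grid])
    return float(np.sum(np.abs(cdf_x - cdf_y)[:-1] * np.diff(grid)))


class TestOllivierRicci:
    def make(self, g):
        return dsc.ContactGraph(graph=g, cutoff=1.0)

    def test_single_edge_zero(self):
        cg = self.make(nx.path_graph(2))
        assert dsc.ollivier_ricci_node(cg, 0) == pytest.approx(0.0)

    def test_triangle_half(self):
        cg = self.make(nx.cycle_graph(3))
        for v in range(3):
            assert dsc.ollivier_ricci_node(cg, v) == pytest.approx(0.5)

    def test_six_cycle_flat(self):
        cg = self.make(nx.cycle_graph(6))
        for v in range(6):
            assert dsc.ollivier_ricci_node(cg, v) == pytest.approx(0.0)

    def test_isolated_node_rejected(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        g.add_edge(0, 1)
        g.add_node(2)
        with pytest.raises(ValueError):
            dsc.ollivier_ricci_node(self.make(g), 2)

    def test_w1_against_1d_cdf_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nx_, ny_ = rng.integers(2, 6, size=2)
            sx = np.sort(rng.choice(10, size=nx_, replace=False)).astype(float)
            sy = np.sort(rng.choice(10, size=ny_, replace=False)).astype(float)
            mx = rng.dirichlet(np.ones(nx_))
            my = rng.dirichlet(np.ones(ny_))
            cost = np.abs(sx[:, None] - sy[None, :])
            assert dsc.wasserstein_1(mx, my, cost) == pytest.approx(
                oracle_w1_1d(mx, my, sx, sy), abs=1e-8)


class TestMultifractalDimension:
    def make(self, g):
        return dsc.ContactGraph(graph=g, cutoff=1.0)

    def test_path_interior_matches_regression_oracle(self):
        cg = self.make(nx.path_graph(9))
        # closed-form least squares on log(3,5,7) vs log(1,2,3)
        x = np.log([1.0, 2.0, 3.0])
        y = np.log([3.0, 5.0, 7.0])
        slope = (((x - x.mean()) * (y - y.mean())).sum()
                 / ((x - x.mean()) ** 2).sum())
        got = dsc.multifractal_dimension_node(cg, 4, r_max=3)
        assert got == pytest.approx(slope, abs=1e-9)
        assert got == pytest.approx(0.7676, abs=1e-3)

    def test_star_center_saturation(self):
        g = nx.star_graph(7)      # center 0, 7 leaves
        cg = self.make(g)
        x = np.log([1.0, 2.0])
        y = np.log([8.0, 8.0])    # ball saturates at the full graph
        slope = (((x - x.mean()) * (y - y.mean())).sum()
                 / ((x - x.mean()) ** 2).sum())
        assert dsc.multifractal_dimension_node(cg, 0, r_max=2) == \
            pytest.approx(slope, abs=1e-9)

    def test_relabeling_invariance(self):
        g = nx.random_geometric_graph(20, 0.4, seed=2)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        node = list(g.nodes)[0]
        perm = {n: 1000 + i for i, n in enumerate(g.nodes)}
        h = nx.relabel_nodes(g, perm)
        a = dsc.multifractal_dimension_node(self.make(g), node, r_max=3)
        b = dsc.multifractal_dimension_node(self.make(h), perm[node], r_max=3)
        assert a == pytest.approx(b)

    def test_small_component_rejected(self):
        cg = self.make(nx.path_graph(2))
        with pytest.raises(ValueError):
            dsc.multifractal_dimension_node(cg, 0, r_max=2)


class TestDescriptorSet:
    def test_ranges_and_determinism(self, coil):
        a = dsc.compute_descriptor_set(coil, positions=[3, 10, 20])
        b = dsc.compute_descriptor_set(coil, positions=[3, 10, 20])
        for pos in (3, 10, 20):
            row = a.values[pos]
            assert 0.0 <= row["circular_variance"] <= 1.0
            assert 0.0 <= row["pocketness"] <= 1.0
            assert row["min_inaccessible_radius"] >= 0.0
            assert all(np.isfinite(v) for v in row.values())
            np.testing.assert_array_equal(a.vector(pos), b.vector(pos))

    def test_rigid_motion_invariance(self, coil):
        rng = np.random.default_rng(11)
        moved = transform_structure(coil, random_rotation(rng),
                                    rng.standard_normal(3) * 20)
        a = dsc.compute_descriptor_set(coil, positions=[5, 12])
        b = dsc.compute_descriptor_set(moved, positions=[5, 12])
        for pos in (5, 12):
            for name in dsc.RESIDUE_FEATURES:
                tol = 25.0 if name == "accessible_shell_volume" else 1e-5
                assert a.values[pos][name] == pytest.approx(
                    b.values[pos][name], abs=tol), name

    def test_buried_fixture_vs_surface(self, helix, cage):
        helix_set = dsc.compute_descriptor_set(helix, positions=[15])
        cage_set = dsc.compute_descriptor_set(cage, positions=[1])
        assert (cage_set.values[1]["min_inaccessible_radius"]
                > helix_set.values[15]["min_inaccessible_radius"])
        # the caged residue is densely surrounded
        assert (cage_set.values[1]["circular_variance"]
                > helix_set.values[15]["circular_variance"])
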
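"""Geometry- and graph-based residue descriptors on protein structures.

Residue-level descriptors
    circular variance        density/exposure of neighbouring heavy atoms
    OPD chirality index      handedness of the local Cα point cloud
                             (Osipov–Pickup–Dunmur pseudoscalar, G0 variant
                             on unit displacement vectors)
    accessible shell volume  grid volume around the residue a small probe
                             can occupy
    min inaccessible radius  graded burial depth from multiscale probes
    pocketness               fraction of nearby small-probe space that large
                             probes cannot cover (pocket-likeness)
    Ollivier–Ricci curvature optimal-transport curvature of the residue in
                             the Cα contact network
    multifractal dimension   growth exponent of shortest-path balls

Pair-level descriptor
    shortest path distance   hop count between two residues in the contact
                             network

The pocket and multifractal algorithms are documented stand-ins: they follow
the usual multiscale grid-probe and sandbox constructions, with every
parameter exposed. All descriptors are rigid-motion invariant; the OPD index
is a pseudoscalar and is exactly negated by mirror reflection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import linprog
from scipy.spatial import cKDTree

DEFAULT_CONTACT_CUTOFF = 8.0        # Å, Cα–Cα
DEFAULT_CV_RADIUS = 10.0            # Å, heavy atoms around the Cα
DEFAULT_OPD_N = (5, 7, 10, 15)
DEFAULT_GRID_SPACING = 1.0          # Å
DEFAULT_PROBE_RADII = tuple(float(r) for r in range(2, 11))   # 2..10 Å

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

RESIDUE_FEATURES = (
    "circular_variance", "opd_5", "opd_7", "opd_10", "opd_15",
    "accessible_shell_volume", "min_inaccessible_radius", "pocketness",
    "ricci_curvature", "multifractal_dimension",
)


def _vdw(atom_name: str) -> float:
    return VDW_RADII.get(atom_name[0], 1.7)


# ---------------------------------------------------------------------------
# contact graph

@dataclass
class ContactGraph:
    """Simple Cα-contact graph over residue positions."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self):
        return list(self.graph.nodes)

    def __contains__(self, position):
        return position in self.graph


def build_contact_graph(structure, cutoff: float = DEFAULT_CONTACT_CUTOFF
                        ) -> ContactGraph:
    """Edge between residues whose Cα–Cα distance is at most ``cutoff`` Å."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca = structure.ca_coords()
    positions = structure.positions
    g = nx.Graph()
    g.add_nodes_from(positions)
    tree = cKDTree(ca)
    for i, j in tree.query_pairs(cutoff):
        g.add_edge(positions[i], positions[j])
    return ContactGraph(graph=g, cutoff=cutoff)


def shortest_path_distance(cg: ContactGraph, i: int, j: int):
    """Hop count between residues i and j; disconnected pairs map to the
    sentinel L+1 (L = number of residues) so downstream features stay finite."""
    g = cg.graph
    for p in (i, j):
        if p not in g:
            raise KeyError(f"position {p} not in contact graph")
    if i == j:
        return 0
    try:
        return nx.shortest_path_length(g, i, j)
    except nx.NetworkXNoPath:
        return g.number_of_nodes() + 1


# ---------------------------------------------------------------------------
# circular variance

def circular_variance(structure, position: int,
                      radius: float = DEFAULT_CV_RADIUS) -> float:
    """1 − ‖Σ_k u_k‖ / n over unit vectors u_k from the residue's Cα to each
    neighbouring heavy atom within ``radius`` (own-residue atoms excluded).

    Near 0: protruding/isolated; near 1: densely surrounded. With zero
    neighbours the residue is maximally exposed and 0 is returned with a
    warning.
    """
    res = structure.residue_at(position)
    center = res.ca
    vecs = []
    for other in structure.residues:
        if other.position == position:
            continue
        for xyz in other.atoms.values():
            v = xyz - center
            d = np.linalg.norm(v)
            if 0 < d <= radius:
                vecs.append(v / d)
    if not vecs:
        warnings.warn(f"no neighbour atoms within {radius} Å of residue "
                      f"{position}; returning 0")
        return 0.0
    vecs = np.asarray(vecs)
    return float(1.0 - np.linalg.norm(vecs.sum(axis=0)) / len(vecs))


# ---------------------------------------------------------------------------
# OPD chirality index

_QUAD_CACHE: dict = {}


def _quadruple_indices(n: int) -> np.ndarray:
    """All ordered quadruples of n points as an (m, 4) index array."""
    if n not in _QUAD_CACHE:
        combos = np.array(list(itertools.combinations(range(n), 4)))
        perms = np.array(list(itertools.permutations(range(4))))
        quads = combos[:, perms].reshape(-1, 4)
        _QUAD_CACHE[n] = quads
    return _QUAD_CACHE[n]


def opd_chirality_g0(points: np.ndarray) -> float:
    """OPD G0 chirality pseudoscalar of a point cloud, averaged over all
    ordered quadruples, with unit-normalised pair displacements.

    Zero for any coplanar configuration; exactly negated by reflection.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 4:
        raise ValueError("OPD index needs at least 4 points")
    diff = points[None, :, :] - points[:, None, :]
    norm = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(norm, 1.0)
    unit = diff / norm[:, :, None]
    q = _quadruple_indices(n)
    a, b, c, d = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    u_ab, u_cd = unit[a, b], unit[c, d]
    u_ad, u_bc = unit[a, d], unit[b, c]
    triple = np.einsum("ij,ij->i", np.cross(u_ab, u_cd), u_ad)
    g = triple * np.einsum("ij,ij->i", u_ab, u_bc) \
        * np.einsum("ij,ij->i", u_bc, u_cd)
    return float(g.sum() / len(q))


def opd_chirality_index(structure, position: int, N: int) -> float:
    """OPD G0 index of the N Cα coordinates nearest to the residue's Cα
    (the residue itself included)."""
    if N < 4:
        raise ValueError("need at least 4 points for a chirality index")
    ca = structure.ca_coords()
    if len(ca) < N:
        raise ValueError(f"structure has fewer than {N} residues")
    center = structure.residue_at(position).ca
    d = np.linalg.norm(ca - center, axis=1)
    order = np.lexsort((structure.positions, d))    # ties -> lower position
    return opd_chirality_g0(ca[order[:N]])


# ---------------------------------------------------------------------------
# multiscale grid-probe pocket descriptors

class _PocketGrid:
    """Per-structure grid of probe clearances and coverability masks.

    Built once per (structure, spacing, probes) and reused by every residue.
    ``clearance[p]`` is the largest probe radius a sphere centred at grid
    point p may have without overlapping any heavy atom (van der Waals
    radii). A point is *coverable* by probe r if it lies inside some validly
    placed probe sphere of radius r (computed with a Euclidean distance
    transform); pockets are small-probe space that large probes cannot cover.
    """

    def __init__(self, structure, spacing: float, probe_radii):
        self.spacing = float(spacing)
        self.probe_radii = tuple(float(r) for r in probe_radii)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if list(self.probe_radii) != sorted(self.probe_radii):
            raise ValueError("probe radii must be ascending")
        atoms, owner = structure.heavy_atoms()
        if len(atoms) >= 3:
            centred = atoms - atoms.mean(axis=0)
            s = np.linalg.svd(centred, compute_uv=False)
            if s[1] < 1e-6 * max(s[0], 1.0):
                warnings.warn("degenerate (collinear) structure; pocket "
                              "descriptors computed anyway")
        # the grid lives in the principal-axis frame of the atom cloud so
        # the descriptors are rigid-motion invariant up to float precision
        # (axes oriented by the sign of the third moment)
        self._centre = atoms.mean(axis=0)
        cov = np.cov((atoms - self._centre).T) if len(atoms) >= 3 \
            else np.eye(3)
        vals, vecs = np.linalg.eigh(cov)
        vecs = vecs[:, ::-1]
        proj = (atoms - self._centre) @ vecs
        skew = (proj ** 3).sum(axis=0)
        flip = np.where(skew < 0, -1.0, 1.0)
        self._frame = vecs * flip
        atoms = proj * flip
        self.atoms = atoms
        self.owner = owner
        self.vdw = np.array([_vdw(name)
                             for r in structure.residues
                             for name in r.atoms], dtype=float)
        margin = self.probe_radii[-1] + 2.0
        lo = atoms.min(axis=0) - margin
        hi = atoms.max(axis=0) + margin
        shape = np.maximum(np.ceil((hi - lo) / self.spacing).astype(int) + 1, 2)
        self.origin = lo
        self.shape = tuple(shape)
        ax = [lo[k] + self.spacing * np.arange(shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=-1)
        tree = cKDTree(atoms)
        # k nearest atoms bound the clearance: the vdw spread (<0.3 Å) is
        # far below typical atom spacing, so a small k is exact in practice
        k = min(6, len(atoms))
        dist, idx = tree.query(pts, k=k, workers=-1)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        self.clearance = (dist - self.vdw[idx]).min(axis=1).reshape(self.shape)
        self.points = pts
        self.grid_tree = cKDTree(pts)
        # per-probe accessible-centre trees and coverability masks
        self.coverable = {}
        self.acc_trees = {}
        for r in self.probe_radii:
            acc = self.clearance >= r
            if not acc.any():
                self.coverable[r] = np.zeros(self.shape, dtype=bool)
                self.acc_trees[r] = None
                continue
            self.acc_trees[r] = cKDTree(pts[acc.ravel()])
            dist_to_acc = distance_transform_edt(
                ~acc, sampling=(self.spacing,) * 3)
            self.coverable[r] = dist_to_acc <= r

    def to_grid(self, xyz: np.ndarray) -> np.ndarray:
        """Map world coordinates into the grid's principal-axis frame."""
        return (np.asarray(xyz, dtype=float) - self._centre) @ self._frame

    def flat_clearance(self):
        return self.clearance.ravel()


def _pocket_grid(structure, spacing, probe_radii) -> _PocketGrid:
    key = (round(float(spacing), 6), tuple(float(r) for r in probe_radii))
    cache = getattr(structure, "_pocket_grid_cache", None)
    if cache is None:
        cache = {}
        structure._pocket_grid_cache = cache
    if key not in cache:
        cache[key] = _PocketGrid(structure, spacing, probe_radii)
    return cache[key]


def pocket_descriptors(structure, position: int,
                       grid_spacing: float = DEFAULT_GRID_SPACING,
                       probe_radii=DEFAULT_PROBE_RADII):
    """Multiscale grid-probe burial/pocket measures for one residue.

    Returns ``(accessible_shell_volume, min_inaccessible_radius, pocketness)``:

    * accessible_shell_volume (Å³): volume of grid points within a 10 Å
      shell of the residue's Cα where the smallest probe fits.
    * min_inaccessible_radius (Å): graded burial depth. With r* the largest
      probe that can touch the residue's surface, the value is
      ``(r_max + 1) − r*``; a fully exposed residue scores the minimum
      ``1``, a residue no probe can touch scores the cap ``r_max + 1``.
    * pocketness ∈ [0, 1]: over shell points the smallest probe can occupy,
      the mean fraction of larger probes that cannot cover the point —
      0 in open space, approaching 1 deep inside pockets.
    """
    grid = _pocket_grid(structure, grid_spacing, probe_radii)
    res = structure.residue_at(position)
    r_small, r_max = grid.probe_radii[0], grid.probe_radii[-1]

    ca_g = grid.to_grid(res.ca)
    shell_idx = np.asarray(grid.grid_tree.query_ball_point(ca_g, 10.0),
                           dtype=int)
    clear = grid.flat_clearance()
    acc_small = shell_idx[clear[shell_idx] >= r_small]
    accessible_shell_volume = float(len(acc_small)) * grid_spacing ** 3

    # largest probe whose validly placed sphere touches this residue
    res_atoms = grid.to_grid(np.array(list(res.atoms.values()), dtype=float))
    res_vdw = np.array([_vdw(a) for a in res.atoms], dtype=float)
    r_reach = 0.0
    for r in grid.probe_radii:
        tree = grid.acc_trees[r]
        if tree is None:
            continue
        d, _ = tree.query(res_atoms, k=1)
        if np.any(d - res_vdw <= r + grid_spacing):
            r_reach = r
    min_inaccessible_radius = float(r_max + 1.0 - r_reach)

    if len(acc_small) == 0:
        pocketness = 0.0
    else:
        larger = [r for r in grid.probe_radii if r > r_small]
        blocked = np.zeros(len(acc_small))
        for r in larger:
            blocked += ~grid.coverable[r].ravel()[acc_small]
        pocketness = float(np.mean(blocked / len(larger)))
    return accessible_shell_volume, min_inaccessible_radius, pocketness


# ---------------------------------------------------------------------------
# Ollivier-Ricci curvature

def wasserstein_1(mu_x, mu_y, cost: np.ndarray) -> float:
    """Exact W1 between two discrete distributions by linear programming."""
    nx_, ny_ = len(mu_x), len(mu_y)
    c = np.asarray(cost, dtype=float).reshape(-1)
    a_eq = []
    b_eq = []
    for i in range(nx_):
        row = np.zeros((nx_, ny_))
        row[i, :] = 1.0
        a_eq.append(row.reshape(-1))
        b_eq.append(mu_x[i])
    for j in range(ny_):
        row = np.zeros((nx_, ny_))
        row[:, j] = 1.0
        a_eq.append(row.reshape(-1))
        b_eq.append(mu_y[j])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def ollivier_ricci_edge(cg: ContactGraph, x, y) -> float:
    """κ(x,y) = 1 − W1(μ_x, μ_y) / d(x,y) with μ_v uniform on the neighbours
    of v (no laziness) and d the hop metric. Values are memoised on the
    graph's edge attributes."""
    g = cg.graph
    if not g.has_edge(x, y):
        raise ValueError(f"({x}, {y}) is not an edge")
    cached = g.edges[x, y].get("ricci")
    if cached is not None:
        return cached
    nbr_x = sorted(g.neighbors(x))
    nbr_y = sorted(g.neighbors(y))
    support = sorted(set(nbr_x) | set(nbr_y))
    # hop distances between the two supports
    dist = {}
    for s in support:
        dist[s] = nx.single_source_shortest_path_length(g, s)
    cost = np.array([[dist[u][v] for v in nbr_y] for u in nbr_x], dtype=float)
    mu_x = np.full(len(nbr_x), 1.0 / len(nbr_x))
    mu_y = np.full(len(nbr_y), 1.0 / len(nbr_y))
    w1 = wasserstein_1(mu_x, mu_y, cost)
    kappa = 1.0 - w1 / 1.0     # adjacent nodes: d(x, y) = 1
    g.edges[x, y]["ricci"] = kappa
    return kappa


def ollivier_ricci_node(cg: ContactGraph, position) -> float:
    """Mean Ollivier-Ricci curvature of the edges incident to a residue."""
    g = cg.graph
    if position not in g:
        raise KeyError(f"position {position} not in graph")
    nbrs = list(g.neighbors(position))
    if not nbrs:
        raise ValueError(f"residue {position} is isolated in the contact graph")
    return float(np.mean([ollivier_ricci_edge(cg, position, y) for y in nbrs]))


# ---------------------------------------------------------------------------
# multifractal (sandbox) dimension

def multifractal_dimension_node(cg: ContactGraph, position, r_max=None) -> float:
    """Local sandbox dimension: least-squares slope of log |B(v,r)| against
    log r for r = 1..r_max, where B(v,r) is the closed shortest-path ball."""
    g = cg.graph
    if position not in g:
        raise KeyError(f"position {position} not in graph")
    component = nx.node_connected_component(g, position)
    if len(component) < 3:
        raise ValueError("component too small for a sandbox dimension")
    if r_max is None:
        sub = g.subgraph(component)
        ecc = nx.eccentricity(sub, v=position)
        r_max = min(5, max(2, ecc))
    if r_max < 2:
        raise ValueError("r_max must be at least 2")
    lengths = nx.single_source_shortest_path_length(g, position, cutoff=r_max)
    counts = []
    for r in range(1, r_max + 1):
        counts.append(sum(1 for d in lengths.values() if d <= r))
    log_r = np.log(np.arange(1, r_max + 1))
    log_b = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(log_r, log_b, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# aggregation

@dataclass
class ResidueDescriptorSet:
    """All residue descriptors for (a subset of) residues of one structure."""

    protein_id: str
    values: dict                     # position -> {feature -> float}
    contact_graph: ContactGraph = None
    feature_names: tuple = RESIDUE_FEATURES

    def vector(self, position: int) -> np.ndarray:
        v = self.values[position]
        return np.array([v[name] for name in self.feature_names])

    def __contains__(self, position):
        return position in self.values


def compute_descriptor_set(structure, positions=None,
                           contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                           cv_radius: float = DEFAULT_CV_RADIUS,
                           opd_n=DEFAULT_OPD_N,
                           grid_spacing: float = DEFAULT_GRID_SPACING,
                           probe_radii=DEFAULT_PROBE_RADII
                           ) -> ResidueDescriptorSet:
    """Compute every residue descriptor for the requested positions
    (default: all residues). Deterministic."""
    if positions is None:
        positions = structure.positions
    cg = build_contact_graph(structure, cutoff=contact_cutoff)
    values = {}
    for pos in positions:
        row = {"circular_variance": circular_variance(structure, pos,
                                                      radius=cv_radius)}
        for n in opd_n:
            key = f"opd_{n}"
            if len(structure) >= n:
                row[key] = opd_chirality_index(structure, pos, n)
            else:
                row[key] = 0.0
        asv, mir, pk = pocket_descriptors(structure, pos,
                                          grid_spacing=grid_spacing,
                                          probe_radii=probe_radii)
        row["accessible_shell_volume"] = asv
        row["min_inaccessible_radius"] = mir
        row["pocketness"] = pk
        row["ricci_curvature"] = ollivier_ricci_node(cg, pos)
        row["multifractal_dimension"] = multifractal_dimension_node(cg, pos)
        values[pos] = row
    return ResidueDescriptorSet(protein_id=structure.protein_id,
                                values=values, contact_graph=cg)
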
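"""Generators for close-packed model structures.

Finite clusters cut from the four classic lattices (HCP, FCC, BCC, SC)
emulate hypothetical atomic clusters with every lattice site occupied;
jittered lattices loosely stand in for the disorder of energy-minimized
Lennard-Jones clusters; random hard-sphere packings and self-avoiding
chain packings stand in for micelle cores and compressed polymer melts.

Two fill rules are provided for lattice clusters. ``radial`` selects the
n_sites lattice points nearest a central site, giving a quasi-spherical
cluster. ``hex_plate`` (HCP only) builds the cluster the way the lattice
is described — complete hexagonal plates stacked in alternating ABAB
order, the last partial plate filled from its axis outward. The plate
construction is the one whose surface statistics match the reference
behavior of the 500-site HCP benchmark cluster (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .graph_stats import ContactGraph
from .spatial_network import CoordinateSet, build_contact_graph

__all__ = [
    "LatticeSpec",
    "generate_lattice_cluster",
    "connect_first_neighbors",
    "generate_hard_sphere_packing",
    "generate_polymer_melt_proxy",
    "hcp_c_over_a",
]

#: ideal HCP axial ratio c/a = sqrt(8/3)
hcp_c_over_a = math.sqrt(8.0 / 3.0)

_LATTICES = ("HCP", "FCC", "BCC", "SC")
_FILL_RULES = ("radial", "hex_plate")


@dataclass(frozen=True)
class LatticeSpec:
    """Recipe for a finite lattice cluster.

    ``spacing`` is the nearest-neighbor distance. ``fill_rule`` chooses
    how the n_sites sites are selected (see module docstring);
    ``hex_shells`` fixes the hexagonal-plate radius in shells (None =
    choose the most isotropic plate automatically). ``jitter_sigma``
    adds isotropic Gaussian noise per coordinate after site selection.
    """

    lattice_type: str
    n_sites: int
    spacing: float = 1.0
    fill_rule: str = "radial"
    hex_shells: int | None = None
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lt = self.lattice_type.upper()
        if lt not in _LATTICES:
            raise ValueError(f"lattice_type must be one of {_LATTICES}")
        object.__setattr__(self, "lattice_type", lt)
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if self.fill_rule not in _FILL_RULES:
            raise ValueError(f"fill_rule must be one of {_FILL_RULES}")
        if self.fill_rule == "hex_plate" and lt != "HCP":
            raise ValueError("hex_plate fill is defined for the HCP lattice")


def _lattice_vectors(lattice_type: str, spacing: float):
    """Primitive vectors and basis offsets scaled to the given
    nearest-neighbor spacing."""
    s = spacing
    if lattice_type == "SC":
        a = s
        prim = np.eye(3) * a
        basis = [np.zeros(3)]
    elif lattice_type == "BCC":
        a = 2.0 * s / math.sqrt(3.0)
        prim = np.eye(3) * a
        basis = [np.zeros(3), np.array([0.5, 0.5, 0.5]) * a]
    elif lattice_type == "FCC":
        a = s * math.sqrt(2.0)
        prim = np.eye(3) * a
        basis = [np.zeros(3),
                 np.array([0.0, 0.5, 0.5]) * a,
                 np.array([0.5, 0.0, 0.5]) * a,
                 np.array([0.5, 0.5, 0.0]) * a]
    else:  # HCP, ABAB stacking at ideal c/a
        a1 = np.array([1.0, 0.0, 0.0]) * s
        a2 = np.array([0.5, math.sqrt(3.0) / 2.0, 0.0]) * s
        a3 = np.array([0.0, 0.0, hcp_c_over_a]) * s
        prim = np.vstack([a1, a2, a3])
        basis = [np.zeros(3),
                 np.array([0.5, math.sqrt(3.0) / 6.0, hcp_c_over_a / 2.0]) * s]
        return prim, basis
    return prim, basis


def _enumerate_sites(lattice_type: str, spacing: float, radius: float
                     ) -> np.ndarray:
    """All lattice sites within ``radius`` of the origin site."""
    prim, basis = _lattice_vectors(lattice_type, spacing)
    # conservative index bound: radius / shortest primitive translation
    shortest = min(np.linalg.norm(v) for v in prim)
    m = int(math.ceil(radius / shortest)) + 2
    rng = np.arange(-m, m + 1)
    ii, jj, ll = np.meshgrid(rng, rng, rng, indexing="ij")
    cells = np.stack([ii, jj, ll], axis=-1).reshape(-1, 3) @ prim
    pts = np.concatenate([cells + b for b in basis])
    keep = np.linalg.norm(pts, axis=1) <= radius + 1e-9
    return pts[keep]


def _sites_per_unit_volume(lattice_type: str, spacing: float) -> float:
    prim, basis = _lattice_vectors(lattice_type, spacing)
    return len(basis) / abs(np.linalg.det(prim))


def _radial_fill(lattice_type: str, spacing: float, n_sites: int) -> np.ndarray:
    density = _sites_per_unit_volume(lattice_type, spacing)
    radius = (3.0 * n_sites / (4.0 * math.pi * density)) ** (1.0 / 3.0)
    pts = _enumerate_sites(lattice_type, spacing, radius * 1.5 + 2 * spacing)
    if len(pts) < n_sites:  # enlarge until enough candidates
        pts = _enumerate_sites(lattice_type, spacing, radius * 3 + 4 * spacing)
    d = np.linalg.norm(pts, axis=1)
    # increasing distance from the central site; equidistant ties broken
    # lexicographically by (z, y, x) for determinism
    order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2], np.round(d, 9)))
    return pts[order][:n_sites]


def _hex_plate_sites(shells: int, spacing: float) -> np.ndarray:
    """A centered hexagonal plate with the given number of shells
    (3 s² + 3 s + 1 sites) in the z = 0 plane."""
    a1 = np.array([1.0, 0.0, 0.0]) * spacing
    a2 = np.array([0.5, math.sqrt(3.0) / 2.0, 0.0]) * spacing
    sites = []
    for i in range(-shells, shells + 1):
        for j in range(-shells, shells + 1):
            if abs(i + j) <= shells:
                sites.append(i * a1 + j * a2)
    return np.asarray(sites)


def _auto_hex_shells(n_sites: int, spacing: float) -> int:
    """Plate radius (in shells) making the stacked cluster most isotropic:
    minimize |plate diameter - stack height| over s."""
    layer_gap = spacing * hcp_c_over_a / 2.0
    best, best_score = 1, float("inf")
    for s in range(1, 40):
        per_layer = 3 * s * s + 3 * s + 1
        n_layers = math.ceil(n_sites / per_layer)
        height = (n_layers - 1) * layer_gap
        diameter = 2 * s * spacing
        score = abs(diameter - height)
        if score < best_score:
            best, best_score = s, score
        if per_layer >= n_sites and s > 2:
            break
    return best


def _hex_plate_fill(spacing: float, n_sites: int, shells: int | None
                    ) -> np.ndarray:
    s = shells if shells is not None else _auto_hex_shells(n_sites, spacing)
    plate = _hex_plate_sites(s, spacing)
    b_offset = np.array([0.5, math.sqrt(3.0) / 6.0, 0.0]) * spacing
    layer_gap = spacing * hcp_c_over_a / 2.0
    layers, total = [], 0
    l = 0
    while total < n_sites:
        lay = plate + np.array([0.0, 0.0, l * layer_gap])
        if l % 2 == 1:
            lay = lay + b_offset
        need = n_sites - total
        if need < len(lay):
            # partial last plate: fill from the plate axis outward,
            # ties broken lexicographically by (y, x)
            cen = lay[:, :2].mean(axis=0)
            d = np.linalg.norm(lay[:, :2] - cen, axis=1)
            order = np.lexsort((lay[:, 0], lay[:, 1], np.round(d, 9)))
            lay = lay[order][:need]
        layers.append(lay)
        total += len(lay)
        l += 1
    pts = np.vstack(layers)
    return pts - pts.mean(axis=0)


def generate_lattice_cluster(spec: LatticeSpec) -> CoordinateSet:
    """A hole-free finite cluster with exactly ``n_sites`` lattice sites.

    Radial fill selects sites by increasing distance from a designated
    central site, so the cluster is compact: every site strictly closer
    to the center than the farthest selected site is included. Jitter,
    if requested, is applied after site selection using a generator
    seeded from ``spec.seed``.
    """
    if spec.fill_rule == "hex_plate":
        pts = _hex_plate_fill(spec.spacing, spec.n_sites, spec.hex_shells)
    else:
        pts = _radial_fill(spec.lattice_type, spec.spacing, spec.n_sites)
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.jitter_sigma, size=pts.shape)
    labels = tuple(f"{spec.lattice_type}{i}" for i in range(len(pts)))
    return CoordinateSet(positions=pts, labels=labels)


def connect_first_neighbors(coords: CoordinateSet, spacing: float,
                            rel_tol: float = 1e-6) -> ContactGraph:
    """Connect first nearest neighbors of an unjittered lattice cluster:
    edge iff distance <= spacing (1 + rel_tol).

    Exact lattice distances tie at the cutoff, so the epsilon-inflated
    rule replaces the strict-inequality contact rule here. Equivalent to
    ``build_contact_graph`` with any r_c between the first- and
    second-shell distances. For jittered or disordered coordinates use
    the RDF-based cutoff instead.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    cutoff = spacing * (1.0 + rel_tol)
    tree = cKDTree(coords.positions)
    edges = {(min(i, j), max(i, j)) for i, j in tree.query_pairs(cutoff)}
    return ContactGraph.from_edges(coords.n_points, edges,
                                   labels=coords.labels)


def generate_hard_sphere_packing(n_points: int, min_dist: float,
                                 container_radius: float, seed: int,
                                 max_attempts_per_point: int = 20000,
                                 ) -> CoordinateSet:
    """Random sequential insertion of hard spheres in a spherical container.

    Points are drawn uniformly in the sphere and accepted if at least
    ``min_dist`` from all previous points. Raises when the rejection cap
    is exceeded, reporting the count achieved.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if min_dist <= 0 or container_radius <= 0:
        raise ValueError("min_dist and container_radius must be positive")
    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    cell = min_dist  # uniform grid for neighbor lookups
    grid: dict[tuple[int, int, int], list[int]] = {}

    def cell_of(p):
        return tuple(int(math.floor(c / cell)) for c in p)

    while len(placed) < n_points:
        ok = False
        for _ in range(max_attempts_per_point):
            # uniform in the ball via radius ~ U^(1/3)
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            p = v * container_radius * rng.random() ** (1.0 / 3.0)
            ci, cj, ck = cell_of(p)
            clash = False
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        for idx in grid.get((ci + di, cj + dj, ck + dk), ()):
                            if np.linalg.norm(placed[idx] - p) < min_dist:
                                clash = True
                                break
                        if clash:
                            break
                    if clash:
                        break
                if clash:
                    break
            if not clash:
                grid.setdefault((ci, cj, ck), []).append(len(placed))
                placed.append(p)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"packing infeasible: placed {len(placed)} of {n_points} "
                f"points at min_dist={min_dist} in radius={container_radius}")
    pts = np.asarray(placed)
    return CoordinateSet(positions=pts,
                         labels=tuple(f"S{i}" for i in range(n_points)))


def generate_polymer_melt_proxy(n_chains: int, chain_length: int,
                                bond_length: float, min_dist: float,
                                container_radius: float, seed: int,
                                max_retries: int = 4000,
                                ) -> CoordinateSet:
    """Self-avoiding random-walk chains packed in a sphere.

    Consecutive beads are ``bond_length`` apart; all bead pairs (within
    and across chains) keep at least ``min_dist``; every bead stays
    inside the container. ``chain_ids`` and ``sequence_index`` are
    populated so chain (i, i+1) edges can be exercised downstream.
    """
    if n_chains < 1 or chain_length < 1:
        raise ValueError("need n_chains >= 1 and chain_length >= 1")
    if bond_length <= 0 or min_dist <= 0:
        raise ValueError("bond_length and min_dist must be positive")
    rng = np.random.default_rng(seed)
    beads: list[np.ndarray] = []
    chain_ids: list[str] = []
    seq_index: list[int] = []

    def clashes(p, skip_last: int | None = None) -> bool:
        if np.linalg.norm(p) > container_radius:
            return True
        for idx, q in enumerate(beads):
            if idx == skip_last:
                continue
            if np.linalg.norm(q - p) < min_dist:
                return True
        return False

    for c in range(n_chains):
        for attempt in range(max_retries):
            chain: list[np.ndarray] = []
            # seed bead
            start = None
            for _ in range(max_retries):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                p = v * container_radius * rng.random() ** (1.0 / 3.0)
                if not clashes(p):
                    start = p
                    break
            if start is None:
                raise RuntimeError(
                    f"chain growth failed: no room for a seed bead; completed "
                    f"{c} of {n_chains} chains ({len(beads)} beads placed)")
            chain.append(start)
            beads.append(start)
            grown = True
            while len(chain) < chain_length:
                placed = False
                for _ in range(60):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    p = chain[-1] + v * bond_length
                    # the previous bead sits at bond_length, which may be
                    # below min_dist; it is exempt from the clash test
                    if not clashes(p, skip_last=len(beads) - 1):
                        chain.append(p)
                        beads.append(p)
                        placed = True
                        break
                if not placed:
                    grown = False
                    break
            if grown:
                chain_ids.extend([f"c{c}"] * chain_length)
                seq_index.extend(range(chain_length))
                break
            del beads[len(beads) - len(chain):]  # retract and retry
        else:
            raise RuntimeError(
                f"chain growth failed: completed {c} of {n_chains} chains "
                f"({len(beads)} beads placed)")
    pts = np.asarray(beads)
    return CoordinateSet(positions=pts,
                         labels=tuple(f"b{i}" for i in range(len(pts))),
                         chain_ids=tuple(chain_ids),
                         sequence_index=tuple(seq_index))
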
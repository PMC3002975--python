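"""From 3D coordinates to contact networks.

The pipeline is: compute the radial distribution function g(r) of the
point set, read off the end of the first coordination shell (the first
local minimum after the first peak) as the contact cutoff r_c, and
connect every pair of points closer than r_c. For polymers, consecutive
beads along a chain can additionally be connected regardless of
distance. For proteins, each residue is reduced to a single node at its
Cβ position (Cα for glycine).

Distances use the minimum-image convention when a periodic box is
present; finite clusters are treated in open space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .graph_stats import ContactGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateSet",
    "RadialDistribution",
    "compute_rdf",
    "first_shell_cutoff",
    "build_contact_graph",
    "residue_nodes",
]


@dataclass(frozen=True)
class CoordinateSet:
    """Labeled 3D points, optionally with polymer connectivity and a box.

    ``chain_ids``/``sequence_index`` mark beads along chains so that
    (i, i+1) chain edges can be added; ``box`` holds periodic edge
    lengths (orthorhombic) when the set represents a bulk system.
    """

    positions: np.ndarray
    labels: tuple[str, ...] | None = None
    chain_ids: tuple[str, ...] | None = None
    sequence_index: tuple[int, ...] | None = None
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError("positions must be an N x 3 array with N >= 1")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "positions", pos)
        n = pos.shape[0]
        for name in ("labels", "chain_ids", "sequence_index"):
            val = getattr(self, name)
            if val is not None and len(val) != n:
                raise ValueError(f"{name} length must equal N")
        if self.chain_ids is not None and self.sequence_index is not None:
            by_chain: dict[str, list[int]] = {}
            for cid, s in zip(self.chain_ids, self.sequence_index):
                by_chain.setdefault(cid, []).append(s)
            for cid, seq in by_chain.items():
                if any(b <= a for a, b in zip(seq, seq[1:])):
                    raise ValueError(
                        f"sequence_index not strictly increasing in chain {cid}")
        if self.box is not None:
            if len(self.box) != 3 or any(b <= 0 for b in self.box):
                raise ValueError("box must be three positive edge lengths")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        """Condensed distance vector (minimum image if periodic)."""
        if self.box is None:
            return pdist(self.positions)
        box = np.asarray(self.box)
        out = []
        pos = self.positions
        for i in range(self.n_points - 1):
            d = pos[i + 1:] - pos[i]
            d -= box * np.round(d / box)
            out.append(np.sqrt((d * d).sum(axis=1)))
        return np.concatenate(out) if out else np.empty(0)


@dataclass(frozen=True)
class RadialDistribution:
    """Histogram of pairwise distances normalized by ideal-gas shell counts."""

    bin_edges: np.ndarray
    g: np.ndarray
    density: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if len(edges) != len(g) + 1:
            raise ValueError("need len(bin_edges) == len(g) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must increase")
        if np.any(g < 0):
            raise ValueError("g(r) must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "g", g)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_rdf(coords: CoordinateSet, bin_width: float = 0.1,
                r_max: float = 10.0) -> RadialDistribution:
    """Radial distribution function g(r) of the point set.

    Pair counts per shell are normalized by N * (4/3)π(r₂³ - r₁³) * ρ / 2
    with ρ the mean number density: in a periodic box, N/V; for a finite
    cluster, N divided by the volume of the bounding sphere around the
    centroid. For finite clusters g(r) is therefore meaningful only for
    locating peak/minimum positions, which is all the cutoff selection
    needs.
    """
    if coords.n_points < 2:
        raise ValueError("need at least two points for an RDF")
    if not (0 < bin_width < r_max):
        raise ValueError("require r_max > bin_width > 0")
    if coords.box is not None:
        half = min(coords.box) / 2.0
        if r_max > half:
            raise ValueError(
                f"r_max={r_max} exceeds half the smallest box edge ({half})")
        volume = float(np.prod(coords.box))
    else:
        center = coords.positions.mean(axis=0)
        radius = float(np.linalg.norm(coords.positions - center, axis=1).max())
        radius = max(radius, bin_width)
        volume = 4.0 / 3.0 * np.pi * radius ** 3
    n = coords.n_points
    density = n / volume

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    d = coords.pairwise_distances()
    counts, _ = np.histogram(d, bins=edges)
    shell_volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * n * density * shell_volumes
    g = counts / ideal
    return RadialDistribution(bin_edges=edges, g=g, density=density)


def first_shell_cutoff(rdf: RadialDistribution, smooth_bins: int = 3) -> float:
    """End of the first coordination shell: the first local minimum of
    g(r) after its first peak.

    The histogram is smoothed with a short moving average before the
    extremum search, since raw g(r) of small clusters is jagged.
    """
    g = np.asarray(rdf.g, dtype=float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        g = np.convolve(g, kernel, mode="same")
    centers = rdf.bin_centers

    # first peak: first strict local maximum with non-trivial height
    peak = None
    for i in range(1, len(g) - 1):
        if g[i] > 0 and g[i] >= g[i - 1] and g[i] > g[i + 1]:
            peak = i
            break
    if peak is None:
        raise ValueError("no first coordination shell detected (monotone g(r))")
    for i in range(peak + 1, len(g) - 1):
        if g[i] <= g[i - 1] and g[i] < g[i + 1]:
            return float(centers[i])
    raise ValueError("no minimum after the first peak within r_max")


def _chain_edge_pairs(coords: CoordinateSet) -> list[tuple[int, int]]:
    if coords.chain_ids is None or coords.sequence_index is None:
        raise ValueError("chain_edges requested but chain metadata missing")
    pairs = []
    by_chain: dict[str, list[tuple[int, int]]] = {}
    for idx, (cid, s) in enumerate(zip(coords.chain_ids,
                                       coords.sequence_index)):
        by_chain.setdefault(cid, []).append((s, idx))
    for cid, members in by_chain.items():
        members.sort()
        for (s1, i1), (s2, i2) in zip(members, members[1:]):
            if s2 == s1 + 1:
                pairs.append((i1, i2))
    return pairs


def build_contact_graph(coords: CoordinateSet, r_c: float,
                        chain_edges: bool = False) -> ContactGraph:
    """Adjacency A_ij = 1 iff the pair is closer than r_c (strict).

    With ``chain_edges`` on, consecutive sequence neighbors within each
    chain are connected regardless of distance — the (i, i+1) bonds of a
    polymer are always present. Minimum-image distances are used when a
    periodic box is set.
    """
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    n = coords.n_points
    edges: set[tuple[int, int]] = set()
    if coords.box is None:
        tree = cKDTree(coords.positions)
        for i, j in tree.query_pairs(r_c):
            d = float(np.linalg.norm(coords.positions[i] - coords.positions[j]))
            if d < r_c:  # query_pairs uses <=; the contact rule is strict
                edges.add((min(i, j), max(i, j)))
    else:
        d = squareform(coords.pairwise_distances())
        ii, jj = np.where(np.triu(d < r_c, k=1))
        edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
    if chain_edges:
        for i, j in _chain_edge_pairs(coords):
            edges.add((min(i, j), max(i, j)))
    return ContactGraph.from_edges(n, edges, labels=coords.labels)


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def residue_nodes(structure) -> CoordinateSet:
    """One node per standard amino-acid residue of a parsed structure.

    Node position is the Cβ atom, falling back to Cα for glycine and for
    residues with a missing Cβ (logged). Heteroatoms and waters are
    excluded; only the first model is used. Altloc duplicates resolve to
    the atom Biopython selects as representative.
    """
    model = next(iter(structure))
    positions, labels, chain_ids, seq_index = [], [], [], []
    for chain in model:
        count_in_chain = 0
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            resname = residue.get_resname()
            if resname not in _STANDARD_AA:
                continue
            atom = None
            if resname != "GLY" and "CB" in residue:
                atom = residue["CB"]
            elif "CA" in residue:
                atom = residue["CA"]
                if resname != "GLY":
                    logger.warning("residue %s %s%d missing CB; using CA",
                                   resname, chain.id, resseq)
            if atom is None:
                logger.warning("residue %s %s%d lacks both CB and CA; skipped",
                               resname, chain.id, resseq)
                continue
            positions.append(atom.get_coord())
            labels.append(f"{chain.id}:{resname}{resseq}{icode.strip()}")
            chain_ids.append(str(chain.id))
            seq_index.append(int(resseq))
            count_in_chain += 1
        if count_in_chain:
            logger.debug("chain %s: %d residue nodes", chain.id, count_in_chain)
    if not positions:
        raise ValueError("no standard amino-acid residues with coordinates")
    return CoordinateSet(
        positions=np.asarray(positions, dtype=float),
        labels=tuple(labels),
        chain_ids=tuple(chain_ids),
        sequence_index=tuple(seq_index),
    )
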
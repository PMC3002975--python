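"""Generating-function theory of nearest-neighbor degree correlations.

The degree distribution p_k of a network is encoded in the generating
function G0(x) = Σ_k p_k x^k, normalized so G0(1) = 1. Moments follow
from the derivative property, ⟨k^n⟩ = [(x d/dx)^n G0](1); in particular
the mean degree is z = G0'(1). Following a randomly chosen edge, the
vertex arrived at has degree distributed proportionally to k p_k, with
mean ⟨k²⟩/z.

Pick a node of degree k and clustering C(k). Each of its k neighbors
carries, on average, b = 2I/k = C(k)(k-1) *backlinks* — edges that
interconnect the neighbors (I = C k(k-1)/2 is the interconnection count
from the clustering definition). A neighbor's remaining *outgoing* edges
are its degree less the arrival link less its backlinks, so the mean
number of outgoing links per neighbor is (1/z) Σ_k' k' p_k' (k'-1)(1-C(k')).
The mean neighbor degree is then

    k_nn(k) = 1 + C(k)(k-1) + (1/z) Σ_k' k' p_k' (k'-1) (1 - C(k')).

The first two limits are immediate: with C ≡ 0 the curve is flat at
⟨k²⟩/z (uncorrelated network), and with constant C it collapses to the
linear law

    k_nn(k) = C k + (1 - C) ⟨k²⟩/z,

with slope C and an intercept set by the degree distribution; for a
Poisson distribution (⟨k²⟩/z = z + 1) this becomes
k_nn(k) = C k + (1 - C)(z + 1). A clustering law that decays with k,
e.g. C(k) = C0 exp(-αk), can produce assortative or disassortative
mixing depending on the decay strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ClusteringLaw",
    "constant_clustering",
    "exponential_clustering",
    "tabulated_clustering",
    "TheorySpec",
    "poisson_spec",
    "KnnCurve",
    "g0_from_pk",
    "moment",
    "g1_edge_followed",
    "backlinks_per_neighbor",
    "knn_theory",
    "knn_linear",
    "knn_poisson",
]

_NORM_TOL = 1e-8
_POISSON_TAIL = 1e-12


@dataclass(frozen=True)
class ClusteringLaw:
    """Clustering coefficient as a function of degree, C(k) in [0, 1]."""

    kind: str
    fn: Callable[[int], float]

    def __call__(self, k: int) -> float:
        return self.fn(k)


def constant_clustering(C: float) -> ClusteringLaw:
    if not 0.0 <= C <= 1.0:
        raise ValueError("clustering coefficient must lie in [0, 1]")
    return ClusteringLaw("constant", lambda k: C)


def exponential_clustering(C0: float, alpha: float) -> ClusteringLaw:
    """C(k) = C0 exp(-α k); decaying clustering with degree."""
    if not 0.0 <= C0 <= 1.0:
        raise ValueError("C0 must lie in [0, 1]")
    return ClusteringLaw("exponential", lambda k: C0 * math.exp(-alpha * k))


def tabulated_clustering(table: Mapping[int, float]) -> ClusteringLaw:
    tbl = dict(table)

    def fn(k: int) -> float:
        try:
            return tbl[k]
        except KeyError:
            raise ValueError(f"no tabulated clustering value for k={k}")

    return ClusteringLaw("tabulated", fn)


@dataclass(frozen=True)
class TheorySpec:
    """A finite-support degree distribution plus a clustering law.

    ``p_k`` maps degree -> probability; it must be normalized within
    tolerance and the clustering law must stay in [0, 1] on the support.
    """

    p_k: Mapping[int, float]
    clustering_law: ClusteringLaw

    def __post_init__(self) -> None:
        pk = {int(k): float(p) for k, p in self.p_k.items() if p != 0.0}
        if not pk:
            raise ValueError("empty degree distribution")
        if any(k < 0 for k in pk):
            raise ValueError("degrees must be non-negative")
        if any(p < 0 for p in pk.values()):
            raise ValueError("probabilities must be non-negative")
        total = sum(pk.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"p_k sums to {total}, not 1")
        object.__setattr__(self, "p_k", pk)
        for k in pk:
            c = self.clustering_law(k)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"clustering law gives C({k})={c} outside [0,1]")

    @property
    def support(self) -> tuple[int, ...]:
        return tuple(sorted(self.p_k))

    @property
    def z(self) -> float:
        """Mean degree ⟨k⟩."""
        return moment(self, 1)

    @property
    def k2(self) -> float:
        """Second moment ⟨k²⟩."""
        return moment(self, 2)

    @property
    def k2_over_z(self) -> float:
        return self.k2 / self.z


def poisson_spec(z: float, clustering_law: ClusteringLaw | None = None,
                 ) -> TheorySpec:
    """Poisson degree distribution of mean z, truncated where the
    cumulative probability exceeds 1 - 1e-12, then renormalized."""
    if z <= 0:
        raise ValueError("mean degree must be positive")
    pk = {}
    k, cum = 0, 0.0
    term = math.exp(-z)
    while cum < 1.0 - _POISSON_TAIL:
        pk[k] = term
        cum += term
        k += 1
        term *= z / k
    total = sum(pk.values())
    pk = {k: p / total for k, p in pk.items()}
    law = clustering_law if clustering_law is not None else constant_clustering(0.0)
    return TheorySpec(p_k=pk, clustering_law=law)


@dataclass(frozen=True)
class KnnCurve:
    """Predicted mean neighbor degree per node degree."""

    degrees: tuple[int, ...]
    knn_theory: tuple[float, ...]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.degrees, self.knn_theory))


def g0_from_pk(spec: TheorySpec) -> np.ndarray:
    """Coefficient sequence of G0(x) = Σ p_k x^k (index = power of x)."""
    kmax = max(spec.support)
    coeffs = np.zeros(kmax + 1)
    for k, p in spec.p_k.items():
        coeffs[k] = p
    return coeffs


def moment(spec: TheorySpec, n: int) -> float:
    """⟨k^n⟩ via the derivative property [(x d/dx)^n G0](1).

    The operator x d/dx acts on the coefficient sequence as c_k -> k c_k
    (a factorial-shift on coefficients, exact — no finite differences);
    evaluating at x = 1 sums the coefficients.
    """
    if n < 1:
        raise ValueError("moment order must be >= 1")
    coeffs = g0_from_pk(spec)
    k = np.arange(len(coeffs))
    for _ in range(n):
        coeffs = coeffs * k
    return float(coeffs.sum())


def g1_edge_followed(spec: TheorySpec) -> np.ndarray:
    """Degree distribution of the vertex reached along a random edge.

    Coefficient at k is k p_k / z: the vertex is reached with probability
    proportional to its degree. The mean of this distribution is ⟨k²⟩/z.
    """
    z = spec.z
    if z <= 0:
        raise ValueError("no edges to follow: distribution concentrated at k=0")
    coeffs = g0_from_pk(spec)
    k = np.arange(len(coeffs))
    return coeffs * k / z


def backlinks_per_neighbor(k: int, C: float) -> float:
    """Mean backlinks per neighbor, b = 2I/k with I = C k(k-1)/2.

    I counts edges interconnecting the k neighbors of a node with
    clustering C; each such edge contributes two backlink end-points, so
    b = C (k - 1). b is an average and need not be an integer.
    """
    if k < 1:
        raise ValueError("backlinks undefined for an isolated node")
    if not 0.0 <= C <= 1.0:
        raise ValueError("clustering coefficient must lie in [0, 1]")
    interconnections = C * k * (k - 1) / 2.0
    return 2.0 * interconnections / k


def _mean_outgoing_per_neighbor(spec: TheorySpec) -> float:
    """(1/z) Σ k p_k (k - 1) (1 - C(k)): degree of the vertex reached along
    an edge, less the arrival link, less its backlinks."""
    z = spec.z
    return sum(k * p * (k - 1) * (1.0 - spec.clustering_law(k))
               for k, p in spec.p_k.items()) / z


def knn_theory(spec: TheorySpec, degrees: Sequence[int]) -> KnnCurve:
    """General k_nn(k): outgoing links per neighbor + backlinks per
    neighbor + the arrival link.

    k_nn(k) = 1 + C(k)(k-1) + (1/z) Σ_k' k' p_k' (k'-1)(1 - C(k')).

    With C ≡ 0 the curve is constant at ⟨k²⟩/z; with constant C it equals
    the linear law of :func:`knn_linear` pointwise.
    """
    outgoing = _mean_outgoing_per_neighbor(spec)
    values = []
    for k in degrees:
        if k < 1:
            raise ValueError("k_nn(k) defined for k >= 1")
        b = backlinks_per_neighbor(k, spec.clustering_law(k))
        values.append(1.0 + b + outgoing)
    return KnnCurve(degrees=tuple(int(k) for k in degrees),
                    knn_theory=tuple(values))


def knn_linear(k: int, C: float, spec: TheorySpec) -> float:
    """Constant-C reduction: k_nn(k) = C k + (1 - C) ⟨k²⟩/z.

    Slope C; the k -> 0 extrapolation of a measured line therefore
    recovers ⟨k²⟩/z as intercept / (1 - slope).
    """
    if not 0.0 <= C <= 1.0:
        raise ValueError("clustering coefficient must lie in [0, 1]")
    return C * k + (1.0 - C) * spec.k2_over_z


def knn_poisson(k: int, C: float, z: float) -> float:
    """Poisson specialization: ⟨k²⟩/z = z + 1, so
    k_nn(k) = C k + (1 - C)(z + 1)."""
    if z <= 0:
        raise ValueError("mean degree must be positive")
    if not 0.0 <= C <= 1.0:
        raise ValueError("clustering coefficient must lie in [0, 1]")
    return C * k + (1.0 - C) * (z + 1.0)
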
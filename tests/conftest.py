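"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive double/triple loops over the dense
adjacency matrix (and Floyd-Warshall for distances) so that they share
no code path with the implementations they check.
"""

import numpy as np
import pytest

from packnet.graph_stats import ContactGraph


def random_graph(n: int, p: float, seed: int) -> ContactGraph:
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return ContactGraph.from_edges(n, edges)


def oracle_degrees(a: np.ndarray) -> np.ndarray:
    a = a.astype(int).tolist()
    n = len(a)
    return np.array([sum(a[i][j] for j in range(n)) for i in range(n)])


def oracle_knn(a: np.ndarray) -> np.ndarray:
    a = a.astype(int)
    n = len(a)
    k = oracle_degrees(a)
    out = np.full(n, np.nan)
    for i in range(n):
        if k[i] == 0:
            continue
        total = 0
        for j in range(n):
            if a[i][j]:
                total += k[j]
        out[i] = total / k[i]
    return out


def oracle_clustering(a: np.ndarray) -> np.ndarray:
    n = len(a)
    k = oracle_degrees(a)
    out = np.full(n, np.nan)
    for i in range(n):
        if k[i] < 2:
            continue
        tri = 0
        for j in range(n):
            for l in range(j + 1, n):
                if a[i][j] and a[i][l] and a[j][l]:
                    tri += 1
        out[i] = 2.0 * tri / (k[i] * (k[i] - 1))
    return out


def oracle_path_lengths(a: np.ndarray) -> np.ndarray:
    n = len(a)
    inf = float("inf")
    d = [[0 if i == j else (1 if a[i][j] else inf) for j in range(n)]
         for i in range(n)]
    for m in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][m] + d[m][j] < d[i][j]:
                    d[i][j] = d[i][m] + d[m][j]
    out = np.full(n, np.nan)
    for i in range(n):
        reach = [d[j][i] for j in range(n) if j != i and d[j][i] < inf]
        if reach:
            out[i] = sum(reach) / len(reach)
    return out


def oracle_ols(x, y):
    """Closed-form normal-equation OLS with standard errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    s2 = (resid ** 2).sum() / (n - 2) if n > 2 else 0.0
    slope_se = np.sqrt(s2 / sxx)
    intercept_se = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, slope_se, intercept_se


@pytest.fixture(scope="session")
def hcp500():
    """The 500-site HCP reference cluster and its first-neighbor network."""
    from packnet.structure_generators import (LatticeSpec,
                                              connect_first_neighbors,
                                              generate_lattice_cluster)
    spec = LatticeSpec(lattice_type="HCP", n_sites=500, fill_rule="hex_plate")
    coords = generate_lattice_cluster(spec)
    graph = connect_first_neighbors(coords, spacing=1.0)
    return coords, graph
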
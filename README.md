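# packnet

Contact-network analysis of close-packed atomic and molecular
structures: folded proteins reduced to residue networks, micelle cores,
atomic clusters, lattice clusters, and compressed polymer models.

Dense packing constrains how many neighbors a node can have (excluded
volume) and forces neighbors of a node to touch each other (clustering).
`packnet` quantifies how these local constraints produce **assortative
mixing** — the tendency of high-degree nodes to connect to other
high-degree nodes — and tests an analytical prediction connecting the
two.

## The model

For a simple undirected contact graph, define per node *i* the degree
*k<sub>i</sub>*, the mean neighbor degree *k<sub>nn,i</sub>*, and the
clustering coefficient *C<sub>i</sub>* = 2*I<sub>i</sub>* /
[*k<sub>i</sub>*(*k<sub>i</sub>* − 1)], where *I<sub>i</sub>* counts
edges among the neighbors of *i*.

Encode the degree distribution *p<sub>k</sub>* in the generating
function G₀(x) = Σ p<sub>k</sub> x<sup>k</sup> with mean degree
*z* = G₀′(1). A vertex reached along a random edge has degree
distributed ∝ *k p<sub>k</sub>*, with mean ⟨k²⟩/z. Each neighbor of a
degree-*k* node carries on average *b* = *C*(*k*)(*k* − 1) *backlinks*
(edges to the other neighbors), so counting a neighbor's links as
outgoing + backlinks + the arrival link gives

> k<sub>nn</sub>(k) = 1 + C(k)(k − 1) + (1/z) Σ<sub>k′</sub> k′ p<sub>k′</sub> (k′ − 1)(1 − C(k′))

The dependence of clustering on degree is the sole determinant of the
mixing: C ≡ 0 gives a flat curve at ⟨k²⟩/z (uncorrelated), constant
C > 0 gives the linear law

> k<sub>nn</sub>(k) = C·k + (1 − C)·⟨k²⟩/z,

and a decaying C(k) can produce either sign. Fitting a line to a
*measured* k<sub>nn</sub>(k) profile therefore predicts ⟨C⟩ from the
slope and ⟨k²⟩/z from intercept/(1 − slope), both checkable against the
same quantities computed directly from the graph.

## Worked example

```python
import numpy as np
import packnet as pn

# a 500-site HCP cluster: stacked hexagonal plates, ABAB order
spec = pn.LatticeSpec(lattice_type="HCP", n_sites=500, fill_rule="hex_plate")
coords = pn.generate_lattice_cluster(spec)
graph = pn.connect_first_neighbors(coords, spacing=1.0)

fit = pn.analyze_system([graph])
print(f"C_calc   = {fit.C_calc:.3f}   k2z_calc = {fit.k2z_calc:.2f}")
print(f"C_pred   = {fit.C_pred:.3f} ± {fit.C_pred_se:.3f}")
print(f"k2z_pred = {fit.k2z_pred:.2f} ± {fit.k2z_pred_se:.2f}")

k = pn.compute_degrees(graph)
C = pn.compute_clustering(graph)
print(f"C(k=12)  = {np.nanmean(C[k == 12]):.3f}   "
      f"C(k=9) = {np.nanmean(C[k == 9]):.3f}")
```

prints

```
C_calc   = 0.410   k2z_calc = 10.41
C_pred   = 0.410 ± 0.043
k2z_pred = 10.08 ± 0.24
C(k=12)  = 0.364   C(k=9) = 0.412
```

The mean clustering measured on the network (0.410) is recovered by the
slope of the k<sub>nn</sub>-vs-k fit (0.410 ± 0.043), and the measured
second-to-first degree-moment ratio (10.41) by the intercept mapping
(10.08 ± 0.24): the constant-clustering linear theory describes this
close-packed cluster well. Interior nodes (full coordination shell,
k = 12) have the geometric HCP value C = 24/66 ≈ 0.364; lower-degree
surface nodes cluster slightly more strongly.

The same pipeline applies to disordered inputs, where the cutoff comes
from the radial distribution function:

```python
packing = pn.generate_hard_sphere_packing(300, 1.0, 5.0, seed=0)
r_c = pn.first_shell_cutoff(pn.compute_rdf(packing, 0.05, 4.0))
g = pn.build_contact_graph(packing, r_c)
print(pn.edge_degree_correlation(g))   # > 0: assortative
```

and to proteins: `pn.residue_nodes(pn.io.read_pdb("file.pdb"))` places
one node per residue at its Cβ atom (Cα for glycine), conventionally
networked at r_c = 6.7 Å.

## Analysis scripts

The `analysis/` directory holds the numbered drivers of the full study —
structure generation, network construction, profile fits, and theory
curves — each writing tables under `results/`:

```sh
python analysis/01_generate_structures.py
python analysis/02_build_networks.py
python analysis/03_fit_knn_profiles.py
python analysis/04_theory_curves.py
```

A `packnet` console command exposes the same steps
(`generate | build | stats | theory | analyze`).

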
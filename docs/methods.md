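# Methods

## Scope and model

`packnet` studies the degree correlations of contact networks built
from densely packed 3D structures. A contact network places one node
per particle (atom, coarse-grained bead, or amino-acid residue) and an
edge between every pair closer than a cutoff r_c. The working
quantities are the per-node degree k, mean neighbor degree k_nn, the
clustering coefficient C, and the mean shortest-path length L; profiles
of k_nn and C against k, pooled over one or several graphs, are the
objects the theory addresses.

The analytical relation (derivation sketched in the README and in
`packnet.gf_theory`) is

    k_nn(k) = 1 + C(k)(k-1) + (1/z) Σ_k' k' p_k' (k'-1)(1 - C(k'))

built from three bookkeeping terms for the links of a neighbor: the
arrival link, its backlinks to the other neighbors (b = C(k)(k-1),
derived from the clustering definition C = 2I/[k(k-1)] with I the
neighbor-interconnection count), and its outgoing links, estimated from
the edge-followed degree distribution k p_k / z with that vertex's own
backlinks removed. The estimate treats the neighbor's degree as drawn
from the edge-followed distribution independently of k — a mean-field
step that is exact for uncorrelated networks and an approximation
otherwise. Its two limits:

* C ≡ 0: k_nn is constant at ⟨k²⟩/z (classical uncorrelated result);
* C constant in k: k_nn(k) = C k + (1 - C)⟨k²⟩/z.

The second limit is the workhorse. Fitting a line to a measured
averaged k_nn(k) profile yields C_pred = slope and, because the
intercept is (1 - C)⟨k²⟩/z, k2z_pred = intercept / (1 - slope). For a
Poisson degree distribution ⟨k²⟩/z = z + 1 and the line becomes
C k + (1 - C)(z + 1). Note the k -> 0 extrapolation of the line is the
intercept itself, which *underestimates* ⟨k²⟩/z by the factor (1 - C);
the division by (1 - slope) is what makes the prediction unbiased, and
is applied everywhere a prediction is reported.

## Numerical choices

* Generating functions are stored as coefficient sequences; moments use
  the operator x d/dx applied symbolically to coefficients (c_k -> k
  c_k), never finite differences, so moment identities hold to
  round-off.
* Poisson distributions are truncated where the cumulative probability
  exceeds 1 - 1e-12, then renormalized; with that tail the cross-path
  identities (general relation vs linear reduction vs Poisson form)
  hold to 1e-9 relative, the tolerance asserted in the tests.
* Undefined descriptors — k_nn of an isolated node, C for k < 2, L in a
  singleton component — are NaN and excluded from every average.
  Zero-filling would bias ⟨C⟩ downward. Degree bins whose k_nn mean is
  undefined (the k = 0 bin) are likewise dropped from the fit.
* The k_nn-vs-k fit is unweighted ordinary least squares over the
  retained degree bins: the fitted object is the averaged profile (one
  point per degree), matching how such curves are usually drawn. A
  node-weighted variant (`fit_knn_nodes`) is provided for sensitivity
  analysis. Standard errors are the usual OLS estimates; the error on
  k2z_pred propagates slope and intercept errors including their
  covariance (cov = -mean(k) var(slope)).
* Degree-bin exclusion presets mirror common practice for sparse bins:
  `rn` drops bins with fewer than 25 pooled nodes; `mn` retains degrees
  5..15 and `mn_text` 4..15 (two circulating variants of the same rule;
  neither is privileged); default is no exclusion.
* Dispersions in degree profiles are sample standard deviations.

## From coordinates to networks

* The contact rule is strict (distance < r_c). Perfect lattices tie
  exactly at the nearest-neighbor distance, so lattice clusters use the
  epsilon-inflated first-nearest-neighbor rule instead: edge iff
  distance <= spacing (1 + 1e-6). Any r_c strictly between the first
  and second shell distances produces the identical network.
* g(r) is a pairwise-distance histogram normalized by ideal-gas shell
  counts at the set's mean density (box volume when periodic, bounding
  sphere for finite clusters — for clusters only peak/minimum
  *positions* matter, which the normalization does not move). Default
  bin width 0.1 length units (0.05 for reduced-unit systems), r_max 10.
* r_c is the first local minimum after the first peak of g(r), after a
  3-bin moving-average smoothing; raw small-cluster histograms are too
  jagged for a bare extremum search. For sparse or small systems the
  minimum can be shallow and its located position moves by a bin or
  two; dense systems give a stable cutoff.
* Periodic systems use minimum-image distances (r_max capped at half
  the smallest box edge).
* Residue networks: one node per standard amino acid at its Cβ atom,
  Cα for glycine or when Cβ is missing (logged); heteroatoms, waters
  and non-first models are ignored. Chain (i, i+1) edges are always
  added for polymer/micelle systems and are off by default for
  proteins, where backbone neighbors are nearly always within r_c
  anyway; the flag exposes the choice.

## Synthetic structures and what they stand for

The generators produce the study's model systems without any external
data:

* **Lattice clusters** (HCP, FCC, BCC, SC; nearest-neighbor spacing 1).
  Radial fill takes the n_sites lattice points closest to a central
  site (ties broken lexicographically by (z, y, x)), a deterministic,
  hole-free, quasi-spherical cluster.
* **The 500-site HCP reference cluster** uses the `hex_plate` fill:
  complete centered-hexagon plates stacked in ABAB order at ideal
  c/a = sqrt(8/3), the last partial plate filled from its axis outward.
  The plate radius (4 shells, 61 sites per plate, at N = 500) is chosen
  to make plate diameter and stack height most nearly equal. This is
  the construction matching the verbal description of such clusters —
  hexagonally arranged planes stacked in alternating order — and its
  surface composition, unlike the quasi-spherical radial fill,
  reproduces the known reference statistics of the 500-site cluster
  (fit slope ≈ 0.41 versus ≈ 0.13 for radial fill, whose surface is
  dominated by high-coordination facets). Cluster shape matters this
  much because the low-degree bins of the profile are populated
  entirely by surface nodes.
* **Jittered lattices** (Gaussian per-coordinate noise) loosely emulate
  the disorder of energy-minimized Lennard-Jones clusters; they do not
  reproduce icosahedral motifs or incomplete cores.
* **Hard-sphere packings** (random sequential insertion in a sphere,
  pairwise min_dist enforced) stand in for micelle cores; **self-avoiding
  chain packings** (fixed bond length, global min_dist) for compressed
  melts. Both are random-insertion structures, not equilibrium
  configurations: their densities (volume fraction ≈ 0.3 at the default
  n = 300, min_dist 1, container radius 5) sit well below true
  close-packing, so their mean degrees are lower than those of
  simulated micelles or pressurized melts. They preserve the property
  under study — excluded volume plus dense packing induces assortative
  mixing — which is what the property tests assert; passing them shows
  the mechanism, not agreement with any simulated system's numbers.
* All stochastic generators draw from a single seeded NumPy generator;
  identical parameters (including seed) give bit-identical coordinates.

## Problem sizes

The analysis scripts and test suite run on clusters of 300–500 sites
and packings of 300 points with 10 seeds: large enough that bulk nodes
with full coordination shells exist and profile fits have 8–10 degree
bins, and small enough that the whole study re-runs in well under a
minute.

## Known limitations

* The theory's outgoing-link term is mean-field; for strongly
  correlated or strongly faceted systems the slope of the fitted line
  systematically underestimates ⟨C⟩ (surface nodes cluster more than
  bulk nodes), while ⟨k²⟩/z remains well predicted — visible in the
  radial-fill lattice rows of the comparison table.
* First-minimum cutoff detection assumes a resolved first coordination
  shell; fluids near the ideal-gas limit fail with a "no shell
  detected" error rather than guessing.
* Graphs are unweighted and undirected throughout; no Voronoi or
  atom-typed contact definitions.
* Disconnected inputs are handled (per-component path lengths, with a
  warning), but the systems of interest are connected.
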
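# Methods

## The diffusion operator

A hypergraph on `n` vertices and `m` hyperedges is stored by its binary
incidence matrix `H` (`n x m`), with diagonal degree matrices `D_V` (row
sums: how many hyperedges contain each vertex) and `D_E` (column sums:
hyperedge cardinalities). The package is restricted to unweighted
hypergraphs, and construction requires every degree to be at least one
(an optional repair mode appends singleton hyperedges to isolated vertices
so that `D_V` stays invertible).

The central object is the column-stochastic diffusion operator

    P_H = H D_E^{-1} H^T D_V^{-1},

the transition matrix of a two-step random walk: from a vertex, pick an
incident hyperedge uniformly, then a member of that hyperedge uniformly.
`P_H` is the top-left `n x n` block of the square of the random-walk matrix
`P~ = A~ D~^{-1}` of the bipartite (star) expansion, whose adjacency is
`[[0, H], [H^T, 0]]`; the bottom-right block is the diffusion operator of
the dual hypergraph (incidence `H^T`). Because `P~` is similar to
`I - L~_N` with `L~_N` the normalized Laplacian of the bipartite graph
(spectrum in `[0, 2]`), the spectrum of `P~` lies in `[-1, 1]` and the
spectrum of `P_H` lies in `[0, 1]`. Two algebraic consequences are used as
standing self-checks: columns of `P_H` sum to one (mass conservation) and
the vertex-degree vector is a fixed point (`P_H d_V = d_V`, since
`H^T 1 = d_E` and `H 1 = d_V`). When every hyperedge has exactly two
vertices, `H H^T = D_V + A_V` gives the lazy random walk
`P_H = (I + A_V D_V^{-1}) / 2` exactly.

Operators are applied only through the factored sparse form (scale by
`D_V^{-1}`, lift with `H^T`, scale by `D_E^{-1}`, push down with `H`), so a
`t`-step diffusion of a `c`-channel signal costs `t * c` sparse
matvecs — `O((d̄_v n + d̄_e m) t c)` arithmetic, where `d̄_v`, `d̄_e` are the
average degrees. A dense realization exists only for instances with
`n + m <= 2000` (configurable) and is used by tests and oracles, never by
the production path. `DiffusionOperator.matvec_count` counts single-column
diffusion steps so the linear-in-scale cost contract is testable by
operation counting rather than wall clock.

## Wavelets

Given integer scales `s_0 <= s_1 <= ... <= s_J` with `s_0 = 0`, `s_1 = 1`,
the filter bank is `Psi_i = P^{s_i} - P^{s_{i+1}}` (band-pass) and
`Phi_J = P^{s_J}` (low-pass). The transform computes `P^s x` incrementally
(one diffusion step at a time, snapshotting at requested scales), so the
total cost is `s_J` matvecs per channel. Since `s_0 = 0`, the bank
telescopes: the filter outputs sum to the input exactly, making the
transform a lossless multiscale decomposition; each filter's spectral
response `lambda^{s_i} - lambda^{s_{i+1}}` lies in `[0, 1]` for
`lambda` in `[0, 1]`.

Defaults: dyadic scales with `J = 4`, i.e. `(0, 1, 2, 4, 8)` — the standard
diffusion-wavelet choice. Tied scales are allowed and produce a zero
filter. Coefficients are kept per filter; flattening concatenates
`Psi_0 .. Psi_{J-1}, Phi_J` per vertex, signed by default with an
entrywise-magnitude mode available (signed coefficients preserve the
telescoping identity and linearity; magnitudes discard sign information
that downstream linear models can use, so signed is the default).

## Spatial lifting

The cell graph `G_0` connects cells whose Voronoi regions touch, computed
via Delaunay triangulation (the planar dual); a symmetrized kNN graph is
the alternative, and degenerate (collinear) inputs fall back to kNN with a
warning. Voronoi regions of hull cells are unbounded, so an optional
`max_edge_length` prune (off by default; the 95th percentile of edge
lengths is a reasonable setting) removes spurious long boundary edges.
Exact duplicate coordinates are jittered by a seeded relative-1e-9
perturbation by default, or rejected.

The k-hop lifting produces exactly one hyperedge per cell — the closed
k-hop neighborhood of that cell — with `k = 3` as the recommended default.
Duplicated neighborhoods are never merged, so hyperedge index = seed cell
index = niche index survives the whole pipeline. Disconnected graphs are
allowed; each component diffuses independently (isolated cells become
singleton hyperedges).

One diffusion step on the lifted hypergraph moves between two members of
one hyperedge, each within `k` hops of its seed, so `d` steps are confined
to graph distance `2kd` on `G_0` (a hard bound, asserted by exact
zero-pattern checks). The nominal receptive field of order `kd` describes
typical reach on regular geometries and is recorded empirically
(`receptive_field_check`), not asserted: on a path graph the `2kd` bound is
attained.

## Niche features and representations

Counts are library-size normalized to 10,000 per cell and
log1p-transformed (all-zero cells stay zero). Four feature families are
computed per hyperedge and concatenated into `z` (one row per niche):

1. mean transformed expression per selected gene;
2. within-hyperedge Pearson correlation for each selected gene pair
   (fixed upper-triangle order);
3. within-hyperedge Pearson correlation between each selected gene and one
   global diffusion step of it;
4. member counts per category at three label granularities (cell type,
   subclass, supertype; sorted vocabularies fixed at construction, unseen
   categories at transform time are an error).

Correlations use the transformed values. Degenerate correlations are 0 by
convention: hyperedges with fewer than three members, and genes whose
within-hyperedge variance is below 1e-12. Computation is vectorized through
per-edge sufficient statistics (`H^T` products of values, squares and cross
products); results are clipped to `[-1, 1]`. The "one step of diffusion"
in family 3 uses the hypergraph operator of the lifted hypergraph by
default; any operator on the same vertex set (e.g. the lazy walk of `G_0`
encoded as a 2-uniform hypergraph) can be passed instead.

The gene subset for families 1–3 defaults to the 30 most variable genes by
transformed variance (ties broken toward the lower index so selection is
stable under cell permutations); all-pairs correlation over a full panel
would be quadratic in panel size. `z` is column-standardized across
hyperedges by default (constant columns map to 0) because the blocks mix
count-scale and correlation-scale values; the raw mode is kept for
cross-sample analyses, where per-tissue standardization would center away
exactly the between-tissue shifts of interest.

Niche representations are the flattened wavelet coefficients `W_J z`
computed on the **dual** hypergraph, whose vertices are the niches; row
`i` of the representation belongs to the niche seeded at cell `i`.
Clustering of niches is spectral clustering on a symmetrized
15-nearest-neighbor connectivity affinity of representation rows,
deterministic given a seed.

## Synthetic tissues

The generator emulates imaging-based spatial transcriptomics of a tissue
section: `n` cells uniform on the unit square; niche regions as Voronoi
cells of random centers (redrawn until every region has at least
`min_cells` cells, so regions are spatially contiguous); cell-type
composition per region = cohort Dirichlet baseline (concentration 5)
tilted by `exp(effect_size * N(0,1))` per region and type; per-type marker
programs (disjoint gene blocks boosted by 1.5 on the log scale); region
modulation of 5 genes per region at `0.15 * effect_size` log-units; counts
negative binomial with dispersion `noise` (variance `mu + noise * mu^2`;
Poisson at 0). At `effect_size = 0` the region label carries no
information about composition or expression.

Cohort-level quantities — the gene baseline and the global composition —
are driven by a separate `panel_seed`, mirroring the fact that tissues
measured with one assay share a gene panel and type programs; the
per-tissue `seed` drives geometry, tilts, modulation and sampling.

A two-level synthetic disease stage is planted in the *spatial
arrangement* of types: stage 0 draws each cell's type independently from
its region composition (mixed neighborhoods), stage 1 assigns types through
sub-territories of roughly 50 cells (locally homogeneous neighborhoods).
Per-cell expression given type and marginal compositions are identical
across stages, so the stage is nearly invisible to single-cell features but
shifts niche-level statistics (within-niche gene-gene correlations,
diffusion smoothness, within-niche type diversity). This mimics niche
reorganization in disease while making "niche-level information" the only
route to the label. A composition-level stage effect was deliberately
avoided: swapping which types co-occur creates an XOR structure in
type-count space that no linear probe can detect, which would make the
niche-vs-raw comparison vacuous.

What the generator does **not** emulate: real gene panels or realistic
cell-type proportions, segmentation errors, spatial expression gradients
within regions, batch effects between tissues, or 3-D geometry. Passing
benchmarks on these tissues demonstrates that the pipeline recovers planted
spatial composition/expression structure under overdispersed count noise;
it does not certify performance on real MERFISH data.

## Benchmarks and known limitations

`evaluation.planted_region_recovery` runs the full default pipeline
(Voronoi graph, k = 3 lift, 30 variable genes, standardized `z`, dyadic
J = 4 wavelets on the dual, spectral clustering with one cluster per
region) and scores adjusted Rand index against the planted regions.
On the easy regime (2000 cells, 50 genes, 6 regions, effect 3.0, noise
0.1) the representation is highly informative in a supervised sense (a
linear probe reaches ~0.95 region accuracy on the mean-expression block
alone), but unsupervised spectral clustering at exactly six clusters
recovers the regions only partially (ARI ~0.5, seeds 0–4). The limitation
is structural rather than numerical: Voronoi regions of random centers are
strongly size-imbalanced while normalized spectral cuts favor balanced
partitions, and overlapping k-hop niches make feature rows vary smoothly
across region boundaries, so the representation-space kNN graph resembles
a 2-D manifold whose natural cuts need not follow region borders. KMeans
on the same representations scores higher (ARI 0.59–0.78), and clustering
the mean-expression block alone is better still; affinity metric, neighbor
count, label assignment, PCA, per-band normalization and magnitude
coefficients were all explored without materially changing the spectral
result. The benchmark keeps spectral clustering as specified and reports
the honest number.

`evaluation.stage_probe_experiment` uses a matched design: per trial,
train/test cohorts of tissue pairs that share seeds (identical geometry
and composition) and differ only in stage. Tissue-disjoint train/test
splits prevent batch memorization. With 3 training and 2 test pairs per
trial, the logistic probe on `W_J z` beats the same probe on raw per-cell
expression by ~0.20 accuracy on average over 5 trials (raw stays at
chance, by construction of the stage effect).

Problem sizes throughout the test-suite benchmarks (up to 2000 cells, 50
genes, batteries of 50 random 30x40 hypergraphs) were chosen so the full
pipeline remains a desk-scale computation; all quantities scale to larger
tissues through the sparse matvec path.

## Numerical conventions

- Stochasticity/eigenvalue/telescoping checks at 1e-9; exact rational
  identities (lazy-walk equivalence) at 1e-12.
- Correlation degeneracy threshold 1e-12 on within-edge variance; outputs
  clipped to `[-1, 1]`.
- Distances on hypergraphs are returned as floats with `inf` for
  unreachable vertices.
- All randomness flows through `numpy.random.default_rng` seeds; spectral
  clustering and probes take explicit seeds.
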
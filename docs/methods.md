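# Methods

`nichetraj` reconstructs a one-dimensional *niche trajectory* — a continuous
axis of tissue-microenvironment variation — from single-cell-resolution
spatial data using only per-cell coordinates and categorical cell-type
labels. No gene-expression values enter the computation, which makes the
method applicable to any segmented spatial assay (MERFISH, Xenium,
stereo-seq, seqFISH, CODEX) once cells are typed.

## Model

**Niche network.** A niche is anchored at each cell and contains the anchor
plus its k nearest neighbors (default k = 50, Euclidean distance in the
sample's coordinate units; 3-D coordinates are supported through an optional
`z` column). Two niches are connected when their anchors are mutual kNN,
giving a symmetric binary adjacency A per sample. Cell i's association with
a niche j containing it is

    w_ij = exp(−d_ij² / σ_j²),

with d_ij the distance to anchor j and σ_j the distance from anchor j to its
20th nearest neighbor (the `sigma_rank` parameter). The niche's composition
vector v_j is the w-weighted fraction of each cell type among its members;
the composition matrix V is row-stochastic. Weights are stored sparsely and
only for member pairs; the anchor always has w = 1, so every niche has
positive total weight. Graphs never cross sample boundaries.

**Encoder and soft clustering.** Compositions are embedded by a two-layer
graph convolution with self-loops and SeLU activations,

    X_t = SeLU((Ã + I) X_{t−1} W_t),  t = 1, 2,  X_0 = V,

where Ã = D^{−1/2} A D^{−1/2} is the symmetrically normalized adjacency
(isolated nodes keep zero rows and are carried by the self-loop). A linear
head soft-assigns each niche to K clusters, C = softmax(β X₂ W_C), with
temperature scale β = 0.03 and K = 6 by default. The training loss is

    L = λ_m L_m + λ_p L_p + λ_r L_r,   λ = (0.3, 300, 0.1),

with the three terms:

- *Modularity* L_m = −Tr(CᵀBC)/2m, B = A − ddᵀ/2m (d = degree vector,
  m = edge count): rewards spatially contiguous clusters.
- *Purity* L_p = (1/NM) Σ_j Σ_t (v_jt − Σ_k c_jk v*_kt)², where v*_k is the
  C-weighted mean composition of cluster k (soft mean, for
  differentiability; empty clusters contribute zero): rewards
  composition-homogeneous clusters.
- *Collapse* L_r = √K/(N(√K−1)) · ‖colsum(C)‖₂: penalizes uneven cluster
  sizes, ranging from 1/(√K−1) (balanced) to √K/(√K−1) (fully collapsed).

Parameters (W₁: M×4, W₂: 4×4, W_C: 4×K by default) are initialized from
N(0, 1/fan-in) with a seeded generator and optimized with Adam
(lr = 0.03, β = (0.9, 0.999)) for up to 1000 epochs. Multiple samples are
trained jointly: a batch of sample graphs is processed as one
block-diagonal graph so the loss normalizations use the batch's total niche
count, and one shared model serves all samples, keeping NT scores
comparable across them. Because the network is tiny, the forward pass,
analytic gradients and Adam are implemented directly in numpy/scipy; the
gradients of all three loss terms (including the dependence of the soft
cluster means on C) are derived in closed form and checked against central
finite differences in the test suite. Seeded runs are bitwise reproducible.

**Modularity normalization.** Two conventions exist for the scale in B and
L_m: the classical edge count 2m and a niche-count 2N variant. The package
defaults to 2m (`modularity_denominator="edges"`): on the synthetic
benchmarks the 2N variant recovers the trajectory only erratically
(Spearman 0.55–0.99 depending on initialization), while 2m is stable at
≈ 0.99 across k ∈ {30, 50}, hidden ∈ {4, 8} and K ∈ {5, 6, 7}. The 2N
variant remains available as `modularity_denominator="nodes"`.

**Trajectory.** The niche network is pooled into a K×K cluster connectivity
E(k,l) = Σ_ij c_ik a_ij c_jl, summed over samples before normalizing
Ẽ(k,l) = E(k,l)/(Σ_i E(k,i) · Σ_i E(i,l)). The trajectory is the
Hamiltonian path p₁→…→p_K maximizing Σ Ẽ(p_k, p_{k+1}); the search is
exact — enumeration of all K!/2 undirected paths for K ≤ 10, Held–Karp
dynamic programming for K ≤ 18 — with ties broken to the lexicographically
smallest path whose first endpoint is below its last. Cluster p_k receives
the score (k−1)/(K−1); niche scores are s_j = Σ_k c_jk s(k) and cell scores
s̃_i = Σ_j w_ij s_j / Σ_j w_ij, so all scores are convex combinations inside
[0, 1]. The path direction is intrinsically arbitrary (reversal mirrors
scores s ↔ 1−s); when a per-cell reference is supplied, scores are flipped
if their Spearman correlation with it is negative, and the orientation flag
records the choice. Branched or circular trajectories are out of scope.

## Synthetic benchmarks

Four generators provide spatial layouts with known per-cell trajectory
coordinates. Cell types are assigned from per-lineage latent times
t ~ U[0, 1] by contiguous equal-width bins, so the type sequence along each
trajectory-bearing lineage is ordered; lineage sizes default to shares
proportional to type counts. Ground truth is always rescaled so its maximum
is exactly 1.

1. **circular** (default 1000 cells, 10 types): lineage 1 (A–G, 70%) sits
   at a uniform angle on the circle of radius t; lineage 2 (H–J, 30%) is
   uniform in the unit disk. Truth = radial distance.
2. **linear** (500 cells): lineage 1 (A–F, 60%) on the x-axis at x = t;
   lineages 2 (G–H) and 3 (I–J) uniform in [0,1] × [−0.25, 0.25]. Truth =
   x-position of the projection onto the axis.
3. **quadratic** (500 cells): lineage 1 on y = a·x² (a = 2 by default;
   the coefficient and region bounds are free parameters chosen once for
   visual distinctness); random lineages uniform in the bounding box.
   Truth = normalized closed-form arc position of the orthogonal projection
   onto the parabola (projection by dense parametric search, 2001 points).
4. **disconnected** (454 cells): two lineages with disjoint type alphabets
   (A–E central, F–J peripheral) in mutually exclusive x-bands separated by
   a gap (default 0.1); x proportional to latent time, y random. Truth =
   rescaled x.

What the generators emulate is the *geometry* of the benchmarks: ordered
type bands along a known 1-D structure plus spatially random "distractor"
lineages. They do not emulate expression noise, cell-type misannotation,
segmentation errors, irregular densities or batch structure, so passing
benchmarks demonstrates correct trajectory recovery under clean geometry,
not robustness to annotation noise in real tissue.

## Evaluation protocol

Recovery is quantified by the orientation-invariant Spearman correlation
(max over the two orientations, i.e. |ρ|) between cell-level NT scores and
ground truth, averaged over three regenerated datasets and training seeds;
constant inputs raise an error rather than returning NaN. Reproducibility
is the matrix of pairwise orientation-invariant correlations across runs.
Per-type density along the trajectory uses a Gaussian KDE (Scott's rule by
default) on a 201-point grid over [0, 1], each curve renormalized to unit
integral; types with fewer than two distinct scores fall back to a narrow
Gaussian bump with a warning.

## Numerical choices and edge cases

- kNN ties are broken by cell index (stable argsort), making graphs
  deterministic; k ≥ sample size is clamped to N−1 with a warning.
- σ_j = 0 (coincident anchors) falls back to the smallest positive member
  distance; all-coincident niches raise an error.
- Zero rows/columns in E yield Ẽ = 0 entries; an all-zero E (degenerate
  clustering) raises an error.
- K = 1 trajectories degenerate to all-zero scores with a warning.
- A non-finite training loss aborts with a diagnostic rather than
  continuing silently.
- Pairwise distances are computed by the dot-product expansion in row
  chunks (bounded memory), accurate to ~1e−13 relative — sufficient since
  distances only enter through ranks and smooth kernels.

## Problem sizes

The shipped benchmarks (≤ 1000 cells, K ≤ 7, 1000 epochs) train in a few
seconds on one CPU core; the full end-to-end suite including the
12-configuration robustness sweep completes in about a minute. Larger
tissues are limited mainly by the O(N²) distance computation and the dense
N×K assignment; hundreds of thousands of cells are feasible but slow in
this pure-numpy implementation.

## Known limitations

- Cell-type annotation granularity directly shapes the trajectory; the
  method cannot recover structure finer than the type alphabet expresses.
- The output is a single unbranched axis; branched or cyclic tissue
  organization is flattened onto it.
- The exact path search is deliberately restricted to K ≤ 18.
- Orientation is arbitrary without a reference; downstream comparisons
  should use orientation-invariant statistics or fix a reference.
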
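# nichetraj

Niche-trajectory analysis of single-cell-resolution spatial omics data.

Tissues are often organized along continuous spatial gradients — cortical
layers, developmental zones, tumor-to-stroma transitions — in which the
local multicellular *niche* changes gradually rather than in discrete
domains. `nichetraj` reconstructs that gradient as a one-dimensional
**niche trajectory (NT)** using only two per-cell inputs: spatial
coordinates and a categorical cell-type label. No gene expression is
needed, so any segmented, cell-typed spatial dataset (MERFISH, Xenium,
stereo-seq, CODEX, ...) works. It is intended for computational biologists
analyzing spatial maps who want a continuous microenvironment coordinate
per cell instead of (or alongside) discrete spatial-domain labels.

## Method

1. **Niche network** — each cell anchors a niche containing its k nearest
   neighbors (k = 50); niches are linked when anchors are mutual kNN
   (adjacency A). Cell–niche association is Gaussian,
   w_ij = exp(−d_ij²/σ_j²) with σ_j the anchor's 20th-neighbor distance,
   and each niche gets a row-stochastic cell-type composition vector v_j.
2. **Graph-convolutional encoding** — X_t = SeLU((Ã + I)X_{t−1}W_t) for
   two layers (hidden dim 4), Ã = D^{−1/2}AD^{−1/2}, X_0 = V.
3. **Soft niche clustering** — C = softmax(βX₂W_C), K = 6 clusters,
   trained with Adam (lr 0.03, ≤ 1000 epochs) on the joint loss
   λ_m·(−Tr(CᵀBC)/2m) + λ_p·‖V − CV*‖²/NM + λ_r·√K‖colsum C‖₂/(N(√K−1)),
   λ = (0.3, 300, 0.1) — modularity for spatial continuity, purity for
   composition homogeneity, and a collapse penalty on cluster sizes.
4. **Trajectory** — clusters are pooled into a connectivity matrix
   E = CᵀAC, normalized, and ordered along the exact maximum-connectivity
   Hamiltonian path; cluster p_k scores (k−1)/(K−1), niches score
   s_j = Σ_k c_jk s(k), and cells score s̃_i = Σ_j w_ij s_j / Σ_j w_ij.
   All NT scores lie in [0, 1]; direction is arbitrary (s and 1−s are
   equivalent) unless a reference is given.

Multiple samples are trained jointly under one shared model, so NT scores
are directly comparable across samples. See `docs/methods.md` for
assumptions, parameter details and limitations.

## Worked example

```python
from nichetraj import NicheTrajectory, simulate_dataset1, spearman_vs_truth

sim = simulate_dataset1(n_cells=1000, seed=0)   # circular benchmark
nt = NicheTrajectory(random_state=0)            # all defaults as above
scores = nt.fit_predict(sim.cells)

print("cluster ordering:", nt.ordering_)
print("cluster scores:  ", nt.cluster_scores_.round(2))
print("first 5 cell NT scores:", scores[:5].round(3))
print("Spearman vs ground truth:", round(spearman_vs_truth(scores, sim.ground_truth), 3))
```

```
cluster ordering: [0 3 5 2 4 1]
cluster scores:   [0.  1.  0.6 0.2 0.8 0.4]
first 5 cell NT scores: [0.17  0.522 0.972 0.986 0.019]
Spearman vs ground truth: 0.992
```

The benchmark lays an ordered 7-type lineage on concentric circles (true
trajectory = radius) with a second, spatially random 3-type lineage mixed
in. The fitted path visits the six niche clusters from the center outward
(cluster 0 scores 0.0, cluster 1 scores 1.0), each cell gets a continuous
position along that axis, and the orientation-invariant Spearman
correlation of 0.992 says the recovered per-cell ordering matches the true
radial coordinate almost perfectly despite 30% of cells carrying no
spatial signal.

The same pipeline is scriptable from the shell:

```bash
nichetraj simulate --dataset 1 --n-cells 1000 --seed 0 --out sim/
nichetraj run --input sim/cells.csv --out results/ --seed 0
nichetraj evaluate --scores results/cell_NT_scores.csv --truth sim/ground_truth.csv
```

`run` writes niche- and cell-level NT scores, soft cluster assignments,
the raw and normalized cluster connectivity, the cluster ordering, and a
JSON manifest that allows bit-for-bit re-execution. Input is a CSV/TSV
with columns `Cell_ID, Sample, Cell_Type, x, y[, z]`.

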
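# Methods

This note documents the models and procedures implemented in
`cytopipe`, the parameters that matter, the numerical choices, and what
the synthetic benchmarks do and do not demonstrate.

## Pre-processing

**cytofAsinh.** Raw CyTOF intensities are transformed per channel as
y = asinh((x − 1)/c) with cofactor c = 5 (the field's standard
variance-stabilizing choice for mass cytometry). Shifted values below
zero — zero-count events — are replaced with a seeded draw from
Normal(0, 0.01²) before the arcsinh, so they stay in a narrow band
around zero rather than forming a spurious negative mode. The
uncensored range x ≥ 1 is exactly asinh((x−1)/5), deterministic and
strictly increasing.

**autoLgcl.** The logicle (biexponential) transform is parameterized
per channel: T = channel maximum, M = 4.5 decades, A = 0, and
linearization width W = (M − log₁₀(T/|q|))/2 where q is the 0.25
quantile of the channel's negative values. Channels with no negatives,
or an estimate outside (0, M/2], fall back to W = 0.1. The forward
transform maps data onto the normalized display scale [0, 1]
(x = T ↦ 1 exactly). The biexponential's internal decay constant d is
solved by bracketed root-finding of w(b+d) + 2(ln d − ln b) = 0 to
1e-12, and each forward value by Brent's method to 1e-10; both are
exercised against closed-form anchor points in the tests.

**Merging.** Transform is applied per file, per channel, *before*
merging (per-file channel ranges differ; merging never re-transforms).
Four strategies: `ceil` (up to N per file, without replacement), `all`,
`min` (the smallest file's count from every file), `fixed` (exactly N,
with replacement where a file is short). One seeded generator is
consumed in file order, making merges reproducible. Cell IDs are
`<file-stem>_<1-based index>`, unique across files; the directory and a
final `.fcs`/`.FCS` extension are stripped so IDs are independent of
storage location.

## FCS I/O

The reader supports FCS 3.0/3.1 list-mode data, `$DATATYPE` I (uniform
8/16/32-bit unsigned) and F (float32), both byte orders, and the
large-file convention of `$BEGINDATA`/`$ENDDATA` in TEXT. `$TOT`,
`$PAR` and the decoded event count are cross-checked; mismatches raise
a parse error naming the keyword. The writer always emits FCS 3.1,
float32, little-endian — one well-tested writer path that mainstream
cytometry software reads — and analysis results (embedding coordinates,
cluster labels) are appended as extra parameters so clusters can be
inspected by conventional gating. Compensation, FCS 2.0 and vendor
dialects are out of scope.

## Embeddings

* **PCA**: full SVD, deterministic.
* **t-SNE**: Barnes-Hut, θ = 0.5, perplexity 30 (error above
  (n−1)/3), 1000 iterations, PCA initialization; inputs with more than
  50 markers are first compressed to 50 principal components. Seeded
  and exactly reproducible.
* **ISOMAP**: k-neighbor graph with k starting at 5 and doubling until
  the graph is connected (classical MDS needs one component); the k
  actually used is recorded in the embedding's params.
* **Diffusion map**: Gaussian kernel exp(−‖x−y‖²/2σ²) with σ = median
  pairwise distance by default; anisotropic α = 1 normalization
  (kernel divided by the product of its row sums) removes
  sampling-density influence so the embedding reflects geometry, not
  abundance; the row-normalized Markov matrix is eigendecomposed via
  its symmetric conjugate, and coordinates are eigenvectors 2..d+1
  scaled by their eigenvalues. Eigenvector signs are fixed
  deterministically (largest-magnitude entry positive).

## ClusterX: density peaks with automatic detection

The neighborhood scale d_c is the 2% quantile of all pairwise
distances (the classic 1–2% guidance for density-peak clustering).
Local density uses the Gaussian kernel ρᵢ = Σ_{j≠i} exp(−(dᵢⱼ/d_c)²);
δᵢ is the distance to the nearest cell with strictly higher density,
with density ties broken by cell index so the nearest-denser pointers
form an acyclic forest rooted at the density-rank maximum (whose δ is
its distance to the farthest cell).

**Peak statistic.** Candidates are scored by σ = √(ρ̃·δ̃), the
geometric mean of min-max-normalized ρ and δ. The product form makes a
cell a peak only when it is simultaneously dense and isolated from
anything denser — δ alone would promote remote stragglers. The square
root is a variance-stabilizing choice: the raw product's background is
so right-skewed that the outlier test below (which assumes an
approximately normal background) systematically over-detects by one to
two peaks; the geometric mean ranks candidates identically while
keeping the background near-normal. On the 600-point, 15-group
benchmark layout the detected peak count is exactly 15 for every
significance level in [0.001, 0.05] and across generator seeds.

**Generalized ESD test.** Peaks are the upper outliers of σ: at step k
the statistic R_k = max(σ − mean)/sd is computed on the progressively
reduced sample, the maximizer removed, and R_k compared with
λ_k = (n−k)·t_{p,n−k−1}/√((n−k−1+t²)(n−k+1)), p = 1 − α/(n−k+1)
(one-sided). The declared peak count is the largest k with R_k > λ_k,
up to `max_outliers` (default 50, capped below n/2). Defaults:
α = 0.001 (the low end of the range over which the peak count should
be — and measurably is — stable); degenerate σ (zero spread) yields a
single peak at the densest cell, as does an empty ESD result, so
assignment is always total.

**Assignment.** Peaks receive labels 1..K in decreasing-density order;
every other cell, visited in decreasing-density order, inherits the
label of its nearest denser neighbor — one pass, no iteration.

**Memory.** ρ, δ and the d_c quantile are computed in row chunks
(default 1000), so the largest allocation is chunk×n, never n×n. The
per-cell reduction order is identical to the full-matrix computation,
so chunked results are bitwise equal to the dense oracle (asserted in
the tests at several chunk sizes).

## PhenoGraph: kNN → Jaccard → Louvain

Exact Euclidean k nearest neighbors (default k = 30, the method's
conventional setting; distance ties broken by index via stable sort).
An edge is evaluated for any pair where either cell lists the other;
its weight is the Jaccard overlap of the two neighbor sets, and
zero-overlap pairs are dropped. Louvain modularity maximization (seeded;
the coarsest level's partition) runs on the weighted graph; communities
are relabeled 1..K by decreasing size, isolated cells become
singletons, and the reported modularity is computed on the returned
partition. Clustering operates on the full marker matrix — no embedding
— so it is the method of choice when the t-SNE map is unreliable.

## DensVM: KDE peaks + SVM completion

A product-Gaussian KDE is evaluated on a 256×256 lattice spanning the
t-SNE map padded by three bandwidths, with the normal-reference rule
per axis (1.06·min(sd, IQR/1.34)·n^(−1/5)). Lattice cells strictly
greater than all eight neighbors and above 1% of the global maximum
are peaks; each peak claims cells within a circle of radius d_k/2
(half the distance to its nearest neighboring peak; a single peak's
radius is half the grid diagonal, covering everything). Cells inside
several circles go to the nearest peak. The remaining cells are
classified by a multi-class SVM (RBF, C = 10, γ = 1/(m·var),
one-vs-one) trained on the *marker profiles* — not the 2-D coordinates
— of the circle-assigned cells; circle assignments are never changed,
and classes with fewer than two training cells are merged into the
nearest class by marker centroid. The historical bandwidth/cluster-
number model-selection scan is deliberately replaced by the single
rule-of-thumb bandwidth: simpler, deterministic, and sufficient for
the separations at which the method is trustworthy anyway.

## Inter-subset relatedness

Clusters are first down-sampled to an equal size (default 500 per
cluster, without replacement) to remove the dominating effect of
large populations, then re-embedded with ISOMAP or diffusion map —
methods that preserve *global* geometry, unlike t-SNE, whose
inter-cluster distances are not reproducible across subsamples (the
stability test quantifies this: Spearman correlation of pairwise
cluster-median distances across three 2/3-subsamples exceeds 0.8 for
both global methods). Cluster positions are coordinate-wise medians.

**Tobit marker trends.** Along a user-annotated ordered path of
clusters, a marker's transformed expression y is regressed on an
embedding component x (optionally sign-reversed to match the annotated
direction) under left censoring at 0 — transformed intensities pile up
at zero, and treating them as exact values biases the slope toward
zero. The likelihood
log L = Σ_{yᵢ>L} log[φ((yᵢ−β₀−β₁xᵢ)/σ)/σ] + Σ_{yᵢ≤L} log Φ((L−β₀−β₁xᵢ)/σ)
is maximized by BFGS on (β₀, β₁, log σ) — the log keeps σ positive —
from an OLS start; if optimization does not improve on the start, the
start is returned with `converged = False`. With nothing censored the
MLE equals OLS (verified to 1e-4). The fit is pooled over the whole
path rather than per segment. Under the benchmark design (n = 2000,
slope 1.5, σ = 1, ~30% censoring) the slope estimate stays within
[1.47, 1.53] across 100 seeded replicates.

## Synthetic benchmarks: what they show

The generators produce seeded Gaussian mixtures in asinh-scale marker
space (means rescaled so the minimum inter-mean distance equals the
requested separation in within-cluster-sd units), a 600-point 2-D
layout of 15 groups (one central, rings of six and eight; sd 0.4
against a minimum center spacing of 3.5, i.e. ≥ 8 sd), and
left-censored linear data with x ~ U(0, 10). They emulate the
*geometry* of well-separated cell populations — not CyTOF noise
physics: no spillover, doublets, acquisition drift or batch effects.
Passing benchmarks therefore demonstrates algorithmic correctness and
calibration, not robustness to instrument artifacts; on real data the
practical failure modes are map fragmentation (t-SNE splitting one
population across islands, which density-peak methods inherit) and
populations closer than a few sd, where all three clusterers begin to
merge or over-split.

Problem sizes used by the test suite and `scripts/acceptance.py` —
2500 cells for the mixture-recovery runs, 600 for the benchmark
layout, 1000–1200 for graph/SVM clustering, 2000×100 replicates for
the censored regression, 3×1333 for embedding stability — were chosen
to keep every statistic stable across seeds while remaining quick to
run on a laptop.

## Known limitations

* FCS reading assumes uniform integer bit widths per file and list
  mode; no compensation/spillover handling.
* ISOMAP embeds only connected neighbor graphs (k grows automatically;
  a graph still disconnected at k = n−1 is an error).
* The ESD peak detector assumes an approximately normal σ background;
  extremely heavy-tailed density landscapes (e.g. fractal-like data)
  may still over-detect.
* Tobit trends assume a linear latent mean and homoscedastic Gaussian
  noise along the chosen component; the "path" is user knowledge, not
  inferred.
* With the `fixed` merge strategy, duplicated cells share a cell ID by
  construction; FCS write-back keeps the last analyzed value for such
  cells.
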
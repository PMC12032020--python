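# Methods

This note documents the models, parameter choices and known limitations of
`gradmosaic`, in the spirit of the methods documentation of established
scientific packages.

## The analysis model

The pipeline treats the cortex as a set of vertices on two spherical
registration surfaces (one per hemisphere) with a mid-wall mask excluding
the medial-wall analogue. Three vertex-by-vertex connectomes are the
inputs:

- **MPC** — depth-wise intensity profiles are cross-correlated with
  partial correlations controlling for the cortex-average profile,
  Fisher r-to-z transformed, and floored at zero. The partial correlation
  uses the closed form
  `r_ij|m = (r_ij − r_im r_jm) / sqrt((1 − r_im²)(1 − r_jm²))`.
  Correlations are clipped to ±(1 − 1e−6) before `atanh` so duplicated
  profiles stay finite without changing any ordering. The zero floor is
  the established MPC convention for the "log transform"; the transform is
  isolated in one function (`fisher_z`) so alternatives are swappable.
- **FC** — Pearson correlation of vertex timeseries with the same clipped
  Fisher transform; signs are kept.
- **SC** — consumed as a nonnegative symmetric matrix (tractography is out
  of scope).

Each matrix is prepared for embedding by keeping the top fraction
(default 0.10) of each row's off-diagonal weights — ties at the cutoff go
to the lower column index, and the operation is idempotent — and
converting row similarity to a normalized-angle affinity,
`1 − arccos(cosine)/π`. Cosine row similarity was chosen for the affinity;
it is invariant to positive row rescaling, which makes the affinity
insensitive to per-vertex scale differences in any modality.

**Diffusion maps.** With `D` the row-sum diagonal of affinity `W`, the
operator `M = D'^{-1} (D^{-α} W D^{-α})` is eigendecomposed through its
symmetric conjugate; the trivial constant eigenvector is dropped and
component i is scaled by `λ_i/(1−λ_i)` (the diffusion-time-0 convention of
the gradient toolboxes this field uses; α = 0.5 by default). Eigenvector
sign is fixed by making the maximum-|value| entry positive, which removes
eigensolver nondeterminism and makes the whole pipeline bit-reproducible
at a fixed seed. A disconnected affinity graph is an error that reports
component sizes.

Hemispheres are embedded jointly on the combined matrix by default. A
split mode (`split_hemisphere_embedding`) embeds each hemisphere
separately and Procrustes-aligns the right gradients to the left;
Procrustes here is a single orthogonal fit after column centering, with no
scaling and no iterative refinement. Multi-subject use goes through
`group_template` (embedding of the entrywise mean connectome — raw
matrices, not affinities, are averaged) as the alignment reference.

**Stacking and arealization.** The first k = 5 gradients per modality
(supported range 3–7) are each divided by their maximum absolute value —
per column, so every gradient spans [−1, 1] and contributes equally — and
concatenated in the fixed order MPC, SC, FC. Vertices take the
highest-probability area of the probabilistic atlas (ties to the lowest
area index; all-zero columns unassigned); per-area means give the
gradient-profile matrix. Areas that lose every vertex are dropped with a
warning rather than zero-filled.

**Statistics.** Inter-areal dissimilarity is the row mean of the
area-by-area cosine-distance matrix; intra-areal dissimilarity is the
cosine distance of each vertex's 15-vector to its own area's mean. Because
area size correlates positively with intra-areal dissimilarity, the
per-area summary is reported both raw and as residuals of a rank-based
linear fit on area vertex count (the exact adjustment is an open choice;
both are exposed). Similarity (1 − cosine distance) feeds average-linkage
agglomerative clustering; the cluster number is chosen by maximum
silhouette over a k range (ties to the smaller k) — silhouette is one of
several reasonable "criterion values" and the interface accepts any
callable alternative. Cross-task diversity computes, per vertex, cosine
distances between whole-brain FC rows across tasks with the vertex's own
diagonal entry removed (a shared exact zero would inflate similarity);
intra-areal cross-task variability is the per-vertex sample SD (ddof = 1)
across tasks of mean within-area FC, averaged over the area's vertices
(the literal "sum divided by vertex count"). For exactness at the
negative control (identical tasks), cosine distance of unit rows is
computed as `‖u−v‖²/2` and the SD is anchored on the first task; both
forms are algebraically identical to the definitions.

**Spin inference.** Area maps are projected to vertices, a uniform random
rotation (QR of a Gaussian 3×3 with det +1) is applied to right-hemisphere
coordinates and its x-mirrored counterpart to the left (preserving
homotopy, the standard spin-test practice), values are resampled by
nearest rotated vertex and re-aggregated under the fixed labeling. This
projection-rotation strategy preserves area count and sizes in every
permutation; the variant that rotates the labeling itself is available
behind `rotate_labels=True`, with areas that lose all vertices yielding a
missing value for that permutation. All permutation p-values use the
`(count+1)/(n+1)` estimator so p is never zero; spin p-values are computed
first and Benjamini–Hochberg FDR is applied across tests afterwards.
Hierarchy contrasts use Student's pooled-variance t (the plain two-sample
t-test), Cohen's d with the pooled SD, and t-based 95% CIs. The
participation coefficient uses positive weights only; zero-strength nodes
get PC 0.

## The synthetic cortex

The generator is an artifact of this package: the study it emulates is
empirical and specifies no generative model, so all distributions here are
design choices documented as such.

- **Mesh** — icosphere per hemisphere (`10·4^L + 2` vertices); tests use
  level 3 (642/hemisphere, 1284 total), chosen so the full pipeline runs
  in seconds while keeping ≥ 30 vertices per area at 40 areas. A
  Fibonacci-lattice mesh provides exact vertex counts, including the
  4432-per-hemisphere study-scale preset. The mid-wall is a fixed polar
  cap (2% of the sphere's area) so exclusion logic is deterministic.
- **Planted axes** — white noise diffused by iterated neighborhood
  averaging until a target correlation length (default 40 mm on a
  100 mm-radius sphere — large enough for a few smooth lobes per
  hemisphere), standardized over cortex. Left and right fields are
  independent.
- **Depth profiles** — a depth-localized Gaussian intensity bump whose
  peak depth moves monotonically along axis 1, on top of a fixed
  decreasing baseline. This makes MPC decay smoothly with axis distance
  *after* residualization on the mean profile; signal shapes that live in
  a 2-D depth subspace collapse to rank 1 under that residualization and
  were deliberately avoided. 12 depths by default (the 14-surface
  convention with the two boundary surfaces dropped).
- **Timeseries** — latent factors with Gaussian-bump loadings over the
  axis; correlation falls off with axis distance. Loadings are computed on
  the rank-uniformized axis with kernel centers extending past both ends,
  which avoids density- and boundary-driven folding of the first
  embedding coordinate. The secondary axis contributes a small (weight
  0.15) loading block. Task scans share latent factors and noise and
  differ only through a per-vertex flexibility field perturbing the axis,
  so zero flexibility gives bit-identical task scans. Default 200
  timepoints, 9 tasks (3 in the smoke configuration).
- **SC** — exponential decay in mirrored-coordinate distance (length scale
  radius/3) times a Gaussian kernel in axis distance, attenuated ×0.2
  across hemispheres, with optional log-normal noise.
- **Annotations** — hierarchy levels are area-level quartiles of axis 1
  (idiotypic → unimodal → heteromodal → paralimbic), giving the four-zone
  analyses a known ground truth; the histological-gradient analogue is the
  area-mean axis plus noise; tSNR is an independent smooth field mapped to
  areas.
- **SNR** — `snr_per_modality` scales additive noise as 1/snr of the
  signal amplitude; `inf` is noise-free. MPC recovery responds strongly
  over snr 8 → 0.5 while FC recovery is additionally limited by
  finite-timepoint sampling noise, so monotonic degradation is assessed
  across that range.

**What the generator does not emulate** — folded cortical geometry,
hemodynamics, realistic noise spectra, subject variability, and distance-
dependent measurement artifacts. Passing tests therefore demonstrate that
the *pipeline* recovers the structure it assumes, not that the assumptions
hold in real MRI.

## Numerical and design choices

- Geodesics are graph shortest paths on edge lengths; exact geodesics are
  unnecessary at generator fidelity. Parcellation labels come from the
  multi-source Dijkstra shortest-path tree on the cortex-only subgraph,
  which guarantees connected Voronoi cells even under the exact distance
  ties a symmetric icosphere produces.
- One master seed fans out to per-stage child seeds by SHA-256 hashing of
  stage names (all below 2³¹), so stages rerun in isolation reproduce the
  full run.
- Reports are written with sorted keys and fixed float formatting; two
  runs at one seed produce byte-identical files. The stored smoke-run
  snapshot is compared at 1e−5 relative tolerance to absorb BLAS
  reduction-order differences.
- Degenerate inputs: constant profiles/timeseries columns are zeroed and
  listed in `excluded`; zero connectivity rows are an error naming the
  vertex; singleton areas score zero intra-areal dissimilarity and are
  flagged; a covariate that fully explains a map yields partial rho
  exactly 0; zero pooled variance flags the contrast and reports d as
  signed infinity.
- In spin-Spearman the x argument is the rotated map by convention; the
  choice is symmetric in expectation.

## Problem sizes used in the checks

Embedding correctness is verified against a full dense nonsymmetric
eigendecomposition on 100–200-vertex affinities (per-component |r| >
0.999). Recovery, dissimilarity-ordering and calibration checks run on the
level-3 mesh with 40 areas: 200 independent smooth-map pairs (300
permutations each) for the Spearman type-I rate, 100 parcellation-
independent maps for the extreme-area flag rate, and ten seeded
end-to-end runs for the intra < inter ordering. These sizes were chosen so
the complete suite runs in a few minutes on one CPU while leaving the
Monte-Carlo error of the calibration estimates well inside the asserted
bands.

## Known limitations

- Spin tests on a parcellated sphere are approximate; nearest-vertex
  resampling duplicates some values and drops others, and calibration is
  slightly conservative rather than exact.
- The SC generator's geometry term dominates its axis term, so the first
  SC gradient recovers the planted axis only partially (as in real data,
  where SC gradients track geometry first); recovery guarantees are
  asserted for MPC and FC only.
- `group_template` averages raw connectomes; averaging affinities instead
  is defensible and would change subject-level alignment slightly.
- GIFTI output covers surfaces, scalar maps and label maps; full CIFTI
  conventions are out of scope.
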
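# Methods

This note documents the model implemented by `nsstruct`, its assumptions,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Representation

A *natural scene structure* (NSS) is a centroid in the space of hexagonal
multi-patch feature vectors. The construction has five stages.

**Dense hexagonal sampling.** Seven circular patches — one central, six
satellites at the vertices of a regular hexagon of side equal to the patch
diameter (tangent circles, so the configuration is non-overlapping by
construction) — are extracted on a regular grid of step `step` pixels, at
each configured diameter. The grid is restricted to the region where the
largest hexagon fits, so every location carries every scale; this is what
makes the cross-scale comparison (same location, two scales, possibly the
same NSS) well defined. Pixel membership of a circle uses the closed-disk
rule r ≤ d/2 on integer offsets, giving the same pixel count *l* for every
patch of a diameter (l = 197 at d = 16). The hexagon is flat-topped with
the first satellite along the +col axis; the orientation is a convention,
not a fitted quantity. Larger diameters are resampled to the smallest by
bicubic interpolation of the bounding square followed by re-masking;
because bicubic resampling is linear in pixel values, it is applied as a
precomputed matrix operator, which keeps batch extraction fast and exactly
reproducible. RGB inputs are converted with Rec.601 luma weights.

**IC basis.** Per scale, FastICA (PCA-whitened, `n_ics` components) learns
analysis filters in pixel space, so a filter's amplitude on a patch is a
plain inner product. Patches are mean-subtracted individually before ICA
and before projection (`center_patches`, on by default) — the standard
pre-normalization for patch ICA; it removes the DC component that ICA
cannot model. Each filter gets a nonlinear least-squares Gabor fit
(8 parameters: amplitude, centre x₀/y₀, envelope scales σx/σy, orientation
θ, frequency f, phase φ). The fit is initialized from the dominant Fourier
component of the filter (orientation, frequency and phase read off the 2-D
FFT peak; envelope centre from the energy centroid) plus a coarse
orientation/frequency multi-start in which amplitude and phase are solved
linearly; the three best starts are refined with Levenberg–Marquardt.
Parameters are canonicalized to σ > 0, θ ∈ [0, π), φ ∈ [0, 2π), f ≥ 0,
A ≥ 0; each reduction adjusts the phase so the rendered function is
unchanged (verified to 1e−8 RMS in the tests). Explained variance r² is
computed against the mean-centred filter.

**IC clustering.** Fitted filters from *all* scales are clustered jointly:
first into 16 equal orientation bins of [0, π), then K-means within each
bin on the 6-vector (x₀, y₀, σx, σy, θ, φ) — the four envelope parameters
plus two carrier parameters; frequency and amplitude are retained as
metadata but are not clustering dimensions, keeping the clustering space at
the stated six parameters. Each dimension is z-scored globally before
K-means because pixels and radians are incommensurate. Per-bin cluster
counts are allocated proportionally to bin occupancy (largest-remainder,
at least one per occupied bin) so the configured total N is met
approximately. Filters whose Gabor fit explains less than r² = 0.5 go to a
single catch-all cluster rather than polluting the parameter clusters.
Identical parameter vectors always share a cluster.

**Projection and codebook.** The feature of patch P for cluster i is the
RMS amplitude over the cluster's same-scale filters,
aᵢ = √((1/m) Σⱼ (P·Aⱼ)²); a cluster with no filter at the patch's scale
contributes 0. The 7 patch vectors concatenate centre-first, satellites
counterclockwise from the +col axis — the order is part of the code. Each
(location, scale) is a separate sample. Per-category K-means (k-means++,
`kmeans_restarts` restarts, tol 1e−4) gives `nss_per_category` centroids;
exact-duplicate centroids are dropped (scikit-learn's K-means relocates
empty clusters instead of returning them, so duplicate removal is the
analogous shrinkage mechanism here). The master book concatenates the
per-category books; assignment is nearest Euclidean centroid with ties to
the lowest index. Selection keeps an NSS iff it occurs (≥ 1 assignment) in
strictly more than M_c training images of at least one category.

**Spatial arrangement.** Occurrences of one NSS in one image are tallied on
an 8×8 grid (cell = (⌊8·row/H⌋, ⌊8·col/W⌋)). Distinct occupied cells n, m
with grid distance L(n, m) < L_c connect with weight min(count_n, count_m).
The distance is Manhattan |Δrow| + |Δcol| by default with Chebyshev
max(|Δrow|, |Δcol|) behind `distance_metric`; both are kept because the
choice is a modelling degree of freedom, and the layout benchmark uses
Chebyshev, whose isotropy in grid steps matches its ring-like spot
geometry. The diagonal is forced to zero: self-connections would add a
trace term that carries no arrangement information and would destroy the
Σλ = 0 contract. The spectral feature is the N_c largest-|λ| eigenvalues
(symmetric eigendecomposition restricted to occupied cells, which is exact
because unoccupied rows/columns are zero), ordered by |λ| then by signed
value, zero-padded.

**Classifier.** Per-image features are the L1-normalized occurrence
frequencies of the selected NSSs concatenated with their eigenvalue blocks.
The 1-χ² kernel requires nonnegative inputs, so each eigenvalue column is
min-max scaled to [0, 1] on the training set (test values clipped); the
kernel is K(x, y) = 1 − Σ (xᵢ−yᵢ)²/(xᵢ+yᵢ) with 0/0 terms contributing 0
(a `variant="half"` switch provides the ½-factor form found elsewhere in
the literature). Multi-class uses one-vs-rest binary C-SVMs on the
precomputed kernel, decided by maximal decision value with ties to the
lowest class index. The headline metric is the mean of the row-normalized
confusion-matrix diagonal (mean per-class accuracy). Five-fold stratified
CV on the training images supports grids over C, M_c, L_c, N_c and the
codebook size; codebooks, selection, spatial features, scaling and the SVM
are refit per fold from the training folds only. The IC basis is learned
once from the training images and not relearned per fold.

## Default parameters

| parameter | default (desk / published profiles) | meaning |
|---|---|---|
| step | 8 / 4 px | sampling grid spacing |
| diameters | (16, 24) px; sports profile adds 32, 46 | patch scales |
| target_diameter | 16 px | common dimensionality after resampling |
| n_ics | 48 / 160 per scale | ICA components |
| n_ic_clusters | 24 / 100 (40 sports) | total IC clusters N |
| nss_per_category | 50 / 1000 (600 sports) | codebook size per category |
| M_c | 7 (sports profile: no selection) | occurrence threshold, images |
| L_c, N_c | 3, 3 (sports: 5, 1) | adjacency range / spectrum length |
| C | 0.125 | SVM regularization |
| ica_patches, codebook_samples | 2×10⁴ | training sample caps |

The `synthetic` profile is the desk-scale configuration used with the
built-in benchmark (256×256 images, ~0.5 k hexagon locations per image):
sample caps of 2×10⁴, 48 ICs, 24 clusters, 50 NSSs per category and
3 K-means restarts keep a full end-to-end run at a few minutes on one CPU
while leaving every stage statistically comfortable (≥ 100 patches per IC,
≥ 400 samples per centroid). The published profiles record the
paper-scale settings (10⁵–10⁶-patch samples, 10 restarts) for use on real
datasets.

## The synthetic benchmark

`make_benchmark` renders three categories that differ in *both* feature
channels: horizontally textured band over a luminance ramp; vertically
textured scattered pillars; centre-clustered isotropic blob field. Textures
are band-pass oriented noise, gratings, Gaussian blob fields and ramps with
additive Gaussian pixel noise (σ = 0.02), fully determined by the recipe
seed. Two *contrast sets* isolate one channel each:

- **satellite**: both categories blend the same coarse and fine isotropic
  blob textures sinusoidally (period 128 px); only the blend axis (rows vs
  columns) differs. A single 16-px circle sees a mixture level whose
  distribution is identical in both classes; only the hexagon's satellites,
  which straddle the gradient, reveal its direction. This isolates the
  concatenation channel: single-circle accuracy sits near chance while the
  hexagon separates the classes.
- **layout**: both categories contain four identical 32-px texture spots on
  384×384 images. Pairwise spot gaps always exceed the 72-px hexagon span,
  so no sample ever sees two spots and the occurrence frequencies match; in
  one class the spots chain with grid gaps below the adjacency range, in
  the other they sit near the corners with gaps of at least three cells.
  Only the adjacency spectra separate the classes, isolating the spatial
  channel.

What passing these tests shows: every stage transmits its intended signal,
the two feature channels are separately sufficient where they should be,
and the pipeline is deterministic under seeds. What it does not show:
performance on natural images — the synthetic textures lack the 1/f
spectra, occlusions, clutter and within-category variability of real
scenes, and the desk-scale codebooks are two orders of magnitude smaller
than the published configurations, so absolute accuracies here do not
transfer.

## Numerical choices and degenerate inputs

- K-means: k-means++ init, 300-iteration cap, tol 1e−4, seeded; restarts
  are a profile parameter.
- Gabor fits that diverge from every start return r² = 0 and are flagged
  unfit (→ catch-all cluster). A constant (DC) filter yields a degenerate
  fit with near-zero frequency.
- ICA on zero-variance patches raises; non-convergence surfaces
  scikit-learn's warning while keeping the best iterate.
- Images too small for one full hexagon yield an empty sample set with a
  warning, not an exception.
- Fisher scores use per-dimension ratios (μ_a−μ_b)²/(σ²_a+σ²_b+ε) with
  ε = 1e−12 summed over the top dimensions; the multi-dimensional extension
  by summation is a design choice (the scalar definition is standard).
- Occurrence matrices with a zero diagonal leave that row unnormalized and
  warn.
- Upsampling in `normalize_scale` is refused; equal-size input is returned
  unchanged.

## Known limitations

- The adjacency distance (Manhattan vs Chebyshev) is a configuration
  switch, not a fitted choice; results can differ between metrics when
  arrangements are diagonal.
- The per-NSS pairwise accuracy uses the same SVM recipe as the main
  classifier; a simpler rule (e.g. a threshold) would be cheaper and may
  behave differently at very low occurrence counts.
- The Gabor parameterization fixes one consistent reading of "four
  envelope + two carrier" clustering parameters (centre + scales +
  orientation + phase); alternatives (scale + aspect ratio) would change
  cluster geometry.
- One-vs-rest with a precomputed kernel stores the full training Gram
  matrix; datasets beyond ~10⁴ images would need chunked kernels.
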
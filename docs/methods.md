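# Methods

## Representational model

Every data source — behavioral ratings, candidate-model embeddings,
motion-energy features, voxel patterns — is reduced to a representational
dissimilarity matrix (RDM): a symmetric, zero-diagonal matrix of pairwise
correlation distances `1 − Pearson r` over conditions, so entries live in
[0, 2].  RDMs are compared by Spearman's rank correlation of their
strictly-upper-triangle vectors in a fixed row-major pair order; average
ranks resolve ties (one-hot RDMs contain exactly two distinct values, so a
tie-tolerant rank transform is mandatory, not cosmetic).

**Variance partitioning.**  A model's unique contribution is the
semi-partial (part) correlation: all vectors are rank-transformed, the
predictor's ranks are residualized by least squares on an intercept plus
the control models' ranks, and the returned statistic is the Pearson
correlation between the *intact* target ranks and the predictor residual.
Residualizing the predictor only (not the target) matches the standard
part-correlation reading of "unique variance explained by this model".
With no controls the statistic reduces exactly to full Spearman.  The
orientation matters: suppression is possible, so |semi-partial ρ| may
exceed |full ρ| — nothing in the code assumes otherwise.

## Neural geometry

Patterns are condition × voxel beta matrices bound to a 3-D grid through
an analysis mask; voxel columns follow the lexicographic order of mask
indices.  Betas are standardized per voxel (zero mean, unit *population*
variance across conditions × repeats within subject — ddof 0, an
arbitrary but documented choice) and averaged across repeats; zero-variance
voxels are zeroed and logged rather than fatal.

- **Searchlights**: one sphere per in-mask voxel, membership
  `x²+y²+z² ≤ r²` in voxel units (inclusive boundary), members restricted
  to the mask; radius 3 gives the 123-point lattice ball.  Spheres with
  fewer than 10 in-mask voxels are flagged, not dropped.  Sphere
  membership and center placement are both restricted to the reliability
  mask.
- **Functional ROIs**: the `ceil(pct·n)` largest localizer-contrast
  voxels inside an anatomical parcel (default pct = 0.10); ties at the
  threshold break by lexicographic voxel order so ROIs are deterministic.
  Overlap between ROIs is quantified by DICE and can be removed
  symmetrically (`a\b`, `b\a`).
- **Reliability**: repeats split even/odd by 0-based index (an odd count
  leaves the extra repeat in the even half).  Per-voxel Pearson r between
  the half-averages across conditions gives the liberal inclusion mask
  r > 0 — subject-specific for ROI analyses, positive group-mean for
  searchlights.  Split-half RSA between the two halves' RDMs, corrected
  by Spearman–Brown `2r/(1+r)`, estimates each region's noise ceiling;
  regions whose ceiling is not significantly above zero (one-tailed
  sign-flip test at α = 0.05) are flagged and excluded from the FDR
  family and from reporting.

## Group inference

Per-subject statistics are tested with a sign-flip permutation test of
the group mean: when `2^n_subjects ≤ n_perm` all sign patterns are
enumerated and p is exact (and seed-invariant); otherwise `n_perm` seeded
patterns are drawn and the observed pattern joins the null count, so
p ≥ 1/(n_perm+1) and the test is valid by construction.  Default
n_perm = 5000, two-tailed for maps, one-tailed for directional ROI
hypotheses.  P-values convert to signed z via the normal quantile of the
FDR-*adjusted* p (the alternative — thresholding raw-p z at a
FDR-derived cutoff — is noted in the run manifest as the ambiguity it
is); maps are written unthresholded and thresholded at |z| ≥ 1.96.
FDR families are explicit per analysis: across voxels for searchlight
maps, across (ROI × model × statistic-kind) cells for ROI tables, across
(model × window) cells per ROI for time-resolved profiles.  Subject ρ
values are not Fisher-z transformed by default; a `fisher_z` switch
exists for sensitivity analyses.

Time-resolved profiles (five windows by default) are compared with a
two-way fully within-subject ANOVA (model × window), each effect tested
against its own subject-by-effect error term with uncorrected degrees of
freedom — 2 models × 5 windows × n subjects gives the interaction df
(4, 4(n−1)); no sphericity correction is applied, and that omission is
deliberate and recorded.

## Feature models

Rating counts per video over (friendly, neutral, adversarial) are
normalized to proportions — counts (8, 0, 2) become (0.8, 0, 0.2) — which
preserves rater ambiguity; single-subject post-scan judgments become
one-hot vectors, whose RDM takes only the values 0 and 1.5.  External
model representations (e.g. a graph-network hidden state or an inverse
planner's category probabilities) are opaque per-condition vectors loaded
from delimited text with strict shape/duplicate validation.

**Motion energy** uses a compact quadrature bank the package defines
itself: complex spatial Gabors (DC-free, σ = size/6) at 3 spatial
frequencies (cycles/image) × 4 orientations, times complex Hann-windowed
temporal exponentials at ±1 and ±2 Hz plus a static low-pass channel.
Temporal kernels with nonzero frequency are forced to zero mean, and only
frame positions with full temporal support are returned, so static input
yields exactly zero motion energy; signed temporal frequencies give
direction selectivity (time-reversing the stimulus swaps the ±f
channels exactly).  Energy is the squared modulus of the full
spatiotemporal response, pooled over pixels.  Per-frame features across
the *whole* stimulus set are PCA-reduced with one shared basis (a
per-video fit would make videos incomparable) and averaged over frames;
retention is either a fixed component count (default 128) or the smallest
count whose cumulative explained variance reaches a target, with the
boundary counted as reached.  An optional log(1+x) transform before PCA
defaults to off.

## Stimulus-subset selection

From a candidate pool with category labels, the selector draws `n_iter`
uniform subsets of size `n_select` without replacement (defaults 1000 and
50), rebuilds the three RDMs on each subset, and scores
`w₂·r(A,beh) + w₃·r(B,beh) − w₁·r(A,B)` with default weights (1, 1, 1);
balance is a hard constraint (max − min category count ≤ 4 by default, a
loose bound consistent with a 16/19/15 split).  The best-scoring feasible
draw wins; an audit table of every draw's component correlations supports
post-hoc inspection.  How the published procedure combined its four
criteria is not knowable from the text; the linear composite with a hard
balance constraint is this package's documented interpretation, and
exhaustive search on small pools confirms the single-criterion special
cases reduce to exact maximization.

## Synthetic ground truth

The generator family produces every input the pipeline reads, with known
truth, through the public I/O path.

- `gen_rating_counts`: multinomial draws per video from given category
  profiles; 10 raters per video by default (the published median),
  overridable per video.
- `gen_model_representations`: three sets (two models + behavior) built
  as a shared latent embedding (8 dims each) plus per-set independent
  noise whose scale is bisected so each set's RDM hits a prescribed
  Spearman correlation with the latent RDM; pairwise couplings follow a
  product rule refined iteratively until the measured pairwise values hit
  the targets — defaults (0.27, 0.50, 0.46), tolerance ±0.05 — emulating
  a stimulus set designed to decorrelate two models while keeping both
  aligned with behavior.
- `gen_pattern_dataset`: each planted region's geometry is the
  weight-blended component RDM, passed through a **rank-uniformizing
  monotone transform** (entries replaced by ranks rescaled to the
  original range).  Spearman-based analyses see identical information;
  uniform spacing makes the re-ranking caused by additive noise or
  subject jitter linear in rank, which keeps a component that is absent
  from the blend truly null through the pipeline's rank-transform
  nonlinearities (without it, the absent component's semi-partial carries
  a small consistent positive bias — a real and documented property of
  semi-partial RSA when model RDMs share latent curvature — which a
  sign-flip test at n = 25 will find).  The blended similarity matrix
  1 − D is factored as a covariance square root (negative eigenvalues
  clipped and logged) and realized on each subject's voxels through a
  random semi-orthogonal frame orthogonal to the constant vector, so the
  noiseless pattern-correlation matrix equals the planted geometry
  exactly per subject.  The summed region weights scale signal amplitude
  in beta units.  With `subject_jitter` τ (default 0.5) each subject's
  true similarity is `(1−τ)·blend + τ·C_s` with an independent random
  correlation geometry `C_s` (rank 10), emulating idiosyncratic
  representational geometry across participants.  Independent
  N(0, σ²) noise is added per repeat (σ = 6.5 by default) and
  out-of-region voxels are pure unit noise.  Defaults — 25 subjects,
  5 repeats, σ = 6.5, τ = 0.5 — were chosen once to land split-half RSA
  ceilings in the 0.05–0.4 range and per-subject semi-partial SDs near
  0.03, the orders of magnitude real social-brain ROIs show; everything
  is bit-reproducible from the seed.
- `gen_windowed_dataset`: five datasets sharing subjects, with per-window
  component weights from `window_schedules` (e.g. rise-and-fall
  (0.3, 0.9, 1.2, 0.9, 0.3) for one model against a gradual increase
  (0.1, 0.4, 0.7, 1.0, 1.3) for the other); noise and frames are
  independent across windows.
- `gen_frame_stack`: a Gaussian blob translating at constant velocity,
  for motion-energy tests with controlled spectra.

**What the generator does not emulate**: spatially correlated noise,
hemodynamic temporal autocorrelation, inter-subject anatomical
misalignment, voxel-scale gain fields, or motion artifacts.  Passing
recovery tests therefore show the *analysis logic* is sound under the
stated generative assumptions, not that effect sizes on real scanners
will match.

## Numerical and degenerate-input conventions

Symmetry and [0, 2] bounds are enforced at 1e-9; RDM ⇄ vector round-trips
are exact.  Constant RDM vectors make rank correlations undefined and
raise; controls collinear with the predictor raise a singularity error
(including the self-control case, where the residual is identically
zero).  Zero-variance feature vectors and condition patterns raise errors
naming the offending condition.  The DICE of two empty masks is an error,
not 0.  Sphere radii are in voxel units with an inclusive boundary.
Problem sizes in the test-suite and acceptance script simulations (20³
grids with 4³ planted regions, 12³ windowed runs, 20–60 seeded
repetitions, 200–2000 permutations) are the package's standard reduced
study conditions; they preserve the 25-subject, 50-condition, 5-repeat
design of the emulated experiment while keeping each run to seconds.

## Known limitations

- Semi-partial control is linear in ranks; when candidate models are
  related through a shared nonlinearity, unique-variance estimates for a
  truly absent model are only asymptotically null (see the rank-uniform
  planting note above).  On real data this residual bias is far below
  inter-subject variability.
- The noise ceiling uses one split (even/odd), not the average over all
  splits, and is therefore itself a noisy estimate at few repeats.
- The sign-flip test assumes subject statistics are symmetrically
  distributed under the null; heavy skew at very small n would
  miscalibrate it.
- No sphericity correction in the repeated-measures ANOVA; with five
  windows, strong non-sphericity would inflate the interaction test.
- Searchlight inference is voxelwise with FDR; no cluster-extent or TFCE
  correction is offered.
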
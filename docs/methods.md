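# Methods

`peritex` models contextual modulation of peripheral texture perception
within the summary-statistics (SS) framework: the peripheral visual input
is represented by a fixed set of texture statistics pooled over a large
window, and task performance is limited by what survives that pooling.
This note documents the model, the numerical choices, and what the
synthetic data can and cannot show.

## Image representation

Images are 2-D luminance arrays in [0, 1] with a pixels-per-degree scale
(default 30 px/deg, the viewing geometry of the modeled experiments;
simulations default to 7.5 px/deg to shrink images fourfold).

### Complex steerable pyramid

The first stage decomposes the image with a polar-separable filter bank
in the frequency domain: raised-cosine radial filters with one-octave
transitions (4 scales) and `cos^3` angular lobes (4 orientations)
restricted to a half-plane, making the oriented bands analytic.  Squared
filter amplitudes tile the spectrum exactly (tight frame), which is
asserted directly on the constructed filter stack and, with the
per-scale frame weights `4^(s-1)`, as exact Parseval energy conservation.
Downsampling is by central spectral cropping (alias-free), with the
"signal" scaling convention (the lowpass of a constant image `c` is `c`).
Boundary handling is circular.  Two discretization facts worth knowing:

* an aligned grating puts 25% of its within-scale energy into the two
  45-degree neighbor bands (`2 cos^6(45°)`), an analytic property of
  order-3 steerable filters, not a bug;
* 90-degree rotation of the input permutes orientation bands exactly at
  full resolution; downsampled scales agree only to ~1e-4 relative
  because the spectral crop of an even grid treats the Nyquist edge
  asymmetrically.

### Summary statistics (782 at defaults)

The second stage computes texture summary statistics over a circular
pooling window, every average weighted by the window resampled (box
average) to the resolution of the map being summarized.  The window
diameter follows Bouma's law: radius = 0.5 x eccentricity, i.e. 360 px
at 12 degrees and 30 px/deg.  The statistic groups, with counts at
(4 scales, 4 orientations, Na = 7):

| group | count |
|---|---|
| pixel marginals (mean, var, skew, kurt, min, max) | 6 |
| skew + kurtosis of lowpass reconstructions, 5 levels | 10 |
| lowpass autocorrelations, 25 unique lags x 5 levels | 125 |
| band-magnitude autocorrelations, 25 x 16 bands | 400 |
| band-magnitude means | 16 |
| within-scale magnitude covariances, 10 x 4 | 40 |
| cross-scale magnitude correlations, 16 x 3 | 48 |
| within-scale real-part covariances, 10 x 4 | 40 |
| cross-scale phase correlations, 4 x 8 x 3 | 96 |
| highpass variance | 1 |
| **total** | **782** |

Deduplication keeps the upper triangle (including diagonal) of symmetric
covariance matrices and the lexicographic half of each centrally
symmetric autocorrelation neighborhood.  Autocorrelations use a
symmetrized window weight so central symmetry is exact; the zero-lag
entry stores the weighted variance and other lags are normalized by it.
Cross-scale statistics correlate each band with its upsampled,
phase-doubled parent (real and imaginary parts), the classic
relative-phase construction.  Lowpass reconstructions use
synthesis-consistent (squared) filters.  Degenerate moments (zero
variance) report skew/kurtosis 0 rather than NaN so classifiers never
see missing values.  The membership above is pinned by the single
constraint that the deduplicated count be exactly 782; the one choice
that constraint forces is that magnitude means cover the 16 oriented
bands, not the residuals.

## Stimulus construction

* **Phase scrambling** replaces the Fourier phases with those of a
  seeded uniform-noise image, preserving the amplitude spectrum (FAS)
  exactly; only the noise phases matter, so the noise distribution is
  immaterial.
* **Histogram matching** is rank-order substitution with stable
  (scan-order) tie breaking.  Texture pairs are co-matched to the
  element-wise mean of their sorted value vectors; the pair-construction
  loop ends on a FAS step so both members share the spectrum to machine
  precision while histograms agree to <1%.
* **Iterative FAS/histogram matching** (30 rounds, ending on the
  histogram step) builds surrounds dissimilar in higher-order statistics
  only (FAS and histogram matched to the target texture) or in FAS as
  well (histogram only).  Convergence is reported, not enforced; the
  structural-similarity preservation term used in some matching
  pipelines is omitted (no parameters are published for it) and a config
  hook is left in its place.
* **Geometry**: disk targets (3.7 degrees default) with ring surrounds
  whose width equals the target diameter (1.4x for the experiment-1
  geometry); gaps of 0.35/0.5 degrees show the gray background and are
  realized either by shrinking the target (surround fixed) or enlarging
  the surround (target fixed) -- identical at gap 0.  Split targets are
  two semicircles with straight sides facing outward, aligned with the
  surround's inner edge (continuity preserved there), the gap carved
  around the curved sides only, preserving texture area.  Half-ring
  surrounds cut the ring at the vertical midline; "inward" is the half
  toward fixation (left, by convention).  Every texture boundary gets a
  linear alpha gradient of 4 px at 30 px/deg (scaled with resolution);
  the surround is composited first and the target over it, so continuous
  boundaries crossfade while gaps show background.

## Model observer

One stimulus pair (left, right; one of {Scr,Nat}, {Nat,Scr}, {Nat,Nat})
per trial.  Predictors are the 782 statistic differences (first minus
second stimulus), each window centered on its target.  Gaussian noise is
added per predictor with SD equal to that predictor's SD over the whole
training set, all conditions pooled -- the stated calibration that
brings model accuracy into the human range (~0.65-0.75 in the control
conditions here); fresh noise is drawn at test time with the same SDs,
drawn independently per trial and predictor.  Predictors are then scaled
to unit variance (divisors frozen from the noisy training set) and
classified by L2-penalized multinomial logistic regression with the
penalty chosen by 10-fold cross-validation over a logarithmic grid
(10 points across 6 decades at desk scale; a finer 50-point grid is a
parameter away).  Full-scale composition is 250 training and 500 test
pairs per class per condition and 8 observer replicates, each with its
own training draws and noise; `scale_factor` shrinks the pair counts
proportionally.

Desk-scale economies, all recorded in run metadata: simulations run at
7.5 px/deg (pooling window 90 px, canvas 128 px); observer replicates
share per-condition stimulus statistic pools, with each replicate
drawing its own pair compositions (with replacement) from disjoint
train/test sub-pools; and accuracy can be evaluated on several times
`n_test` draws from the same pools (`test_draw_factor`) to reduce
test-noise variance at no stimulus cost.

## Behavioral analysis

Trial records reduce to the binary `correct` outcome and are analyzed in
log-odds-ratio (LOR) units.  Sessions below 45% accuracy in **every**
condition are excluded (floor-effect guard).  Per-participant binomial
GLMs give individual Wald LORs.  Group effects come from a binomial
GLMM: for each fixed effect, a random intercept and slope per grouping
factor (texture, and participant nested within texture; participant
only when one texture is analyzed), all random-effect correlations fixed
at zero.  Estimation is by maximum likelihood with a Laplace
approximation, implemented in-package: spherical reparameterization
``u = diag(sd) v`` (robust at zero variances), penalized Newton for the
modes, a bounded quasi-Newton outer loop over the SDs, and a final stage
that moves the fixed effects into the outer Laplace criterion (the
convention of the reference mixed-model software, which the fit matches
to ~3 decimals in cross-checks).  P-values are likelihood-ratio tests of
the effect-deleted model; intervals are profile likelihood with a
flagged Wald fallback.  The LRT is mildly liberal in small samples
(type-I ~0.06-0.07 at nominal 0.05 with ~12 clusters), a known property
of the method, not of this implementation.

## Synthetic data

Procedural textures stand in for photographic-texture syntheses so the
package runs download-free.  Elements (oriented strokes, blobs, or grid
dots) are placed by a clustered Thomas process and modulated by a
smooth log-normal contrast field, because spatial inhomogeneity is the
property of naturalistic textures that phase scrambling destroys and
that drives several model effects: crops of a structured texture vary
more, statistic-wise, than crops of its scramble.  Bright-biased
element amplitudes give the positively skewed histograms typical of
natural textures.  Sources are 1024 px so that independently sampled
target and surround patches rarely overlap (overlapping crops from a
small source let a same-texture surround "echo" the target and bias
surround comparisons).  The behavioral generator is the generative twin
of the GLMM -- baseline logit + condition LORs + Gaussian random
intercepts/slopes per participant and texture, Bernoulli outcomes -- so
parameter recovery can be tested against known ground truth.

What passing tests show: the pipeline reproduces the *directions* of the
robust modeled surround effects (an uninformative surround impairs the
observer; a smaller, gap-separated target impairs it further) and
recovers known LORs from the generative behavioral model.  What they
cannot show: agreement with any specific photographic texture's
statistics, human effect *sizes* (the model observer is noise-matched
only coarsely), or properties of the real behavioral dataset, which is
an optional download this package analyzes but does not bundle.  The
dissimilar-surround and scrambled-surround model effects are small and
vary in sign across procedural textures (see Known limitations), so the
directional tests for them document the target direction rather than a
reproduced result.

## Known limitations

* The 782-statistic membership is one consistent reading of the count;
  other deduplication conventions of the same groups are conceivable.
* Pooling uses a single binary-disk window (raised-cosine edge
  available); multiple tiled windows are out of scope by design.
* The model-observer naturalness and dissimilarity effects depend on
  fine properties of the stimulus-generation process (spatial
  inhomogeneity, the structure retained by the dissimilar surround
  after FAS matching).  With procedural textures they are small and
  texture-dependent even after aggregating over textures and
  replicates, so their directional tests can fail: the effects appear
  for some texture seeds and reverse for others.  Reproducing them
  reliably would require texture sources much closer to the
  photographic-texture syntheses they stand in for.
* Split-target and half-ring geometry follow the written description;
  rendered output should be compared visually against the study's
  figures before any quantitative use of those conditions.
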
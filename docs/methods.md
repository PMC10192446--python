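# Methods

This note documents the models, conventions and parameter choices behind
`scaffoldcount`: what is simulated, how counting is defined, what the
statistics assume, and what the validation suite does and does not show.

## Scaffold and sampling geometry

A scaffold is modelled as an axis-aligned box: the footprint of a 24-well
plate well (15.6 mm diameter) approximated as a 15.6 × 15.6 mm square, with
depth = volume / footprint area (≈ 2.05 mm for the standard 500 µl).
Columns are rectangular and never approach the rim, so replacing the disc by
its bounding box only rescales the depth and leaves the volume-fraction
estimator untouched. Scaffold volume is treated as *measured* (Archimedes
displacement in a 0.1-ml-graduated cylinder: value quantized to 100 µl, raw
difference and the ±0.05 ml reading error retained), not estimated from
imaging.

The sampling design places square fields of area 7/3 mm² on a 3×3 lattice
whose period is footprint/3. All nine fields share one XY offset drawn
uniformly over the slack between field and lattice cell, and one z-start
drawn uniformly over the depths at which the 0.6-mm column fits — systematic
uniform random sampling, which gives every scaffold location equal inclusion
probability and makes the extrapolation unbiased regardless of where cells
actually are.

**Slab convention.** Each of the 30 sections represents a 0.02-mm slab, so a
column's depth is 30 × 0.02 = 0.6 mm and its volume exactly 1.4 µl
(7/3 mm² × 0.6 mm); the field area is back-derived from that volume, since
only the volume is a published constant. Rendered section planes sit at slab
*centres* (z_start + (i+½)h), so the planes tile the slab exactly and the
idealized per-section masks (each nucleus drawn as a disc in the single slab
containing its centre) partition the column's nuclei. All boundaries are
half-open, so tiled columns never double-count a point.

## Synthetic scaffolds

`generate_points` draws exactly *n* nucleus centres (conditioned process —
the count is never random): i.i.d. uniform for a homogeneously mixed
suspension, or a Thomas process (uniform parents, isotropic Gaussian
offspring, offspring assigned to parents multinomially so the total is
exact) as an overdispersed stress case. Offspring falling outside the box
are redrawn from their parent. One integer seed drives each call.

`render_stack` draws each nucleus as an anisotropic Gaussian blob on a noisy
background. Defaults, chosen once as a realistic widefield configuration for
a 10×/0.30 objective and DAPI:

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `pixel_size` | 1.3 | µm | 6.5-µm sCMOS pixel, 10× objective, 2× binning |
| `psf_sigma_xy` | 3.0 | µm | 10-µm nucleus convolved with the lateral PSF → blob FWHM ≈ 7 µm |
| `psf_sigma_z` | 12.0 | µm | widefield barely sections: defocus blur + nucleus size keep nuclei visible ~1 section away; every nucleus in a 20-µm slab is detectable |
| `background_level` / `blob_amplitude` | 100 / 1200 | ADU (16-bit) | bright nuclear stain over dim background |
| `noise_sd` | 80 | ADU | SNR ≈ 15 at peak (Gaussian read-noise model; Poisson available) |

The axial sigma matters: with strong optical sectioning (σ_z ≪ slab
half-width of 10 µm) nuclei centred between planes would be invisible and
the 30-slab volume bookkeeping would undercount; the widefield regime is the
one in which slab-volume accounting is self-consistent.

The simulator does **not** emulate: autofluorescence gradients or scattering
with depth, optical aberrations, photobleaching, uneven staining, nucleus
shape/size variability, or the meniscus/cylindrical scaffold shape. Passing
tests therefore demonstrate correctness of the sampling, counting and
estimation machinery under a faithful geometry and realistic SNR — not
robustness to every imaging artefact of real scaffolds.

## Counting rules

**Counting frame (2D, automated path).** Objects touching the mask's left
(x = 0) or bottom (y = 0) edge are excluded; objects touching the opposite
edges are included. Which pair is exclusionary is a free convention — any
fixed choice is unbiased — and is documented rather than configurable. On a
mask clipped to the frame, edge contact outside the clip is unobservable;
`count_in_frame` additionally implements the frame *inside* a larger
labelled scene with the exclusion-edge extensions (an object is counted iff
it has a pixel in the frame, none below it, and none left of it below the
frame's top). In that form frame counts over tiles are exactly additive for
arbitrary connected objects, which the test suite verifies on random disc
layouts.

**Optical disector (3D path).** Per-section masks are linked across
adjacent sections into 3D objects when cross-sections share pixels (any
overlap by default; a minimum overlap fraction of the smaller cross-section
is available for noisy masks — linkage equals 3D connected components with
in-plane 8-connectivity and face connectivity in z). Each object is counted
once, in the section where it first appears, with the 2D frame rule applied
there; objects already visible in the first supplied mask (the reference or
lookup plane) are never counted. The pipeline acquires that lookup plane
*one z-spacing below the column* (`ColumnSpec.with_lookup_section`), so all
30 column slabs are counted, the disector height equals the column depth,
and the count is unbiased against the 1.4-µl column volume. Feeding the 30
column sections directly (first section doubling as the lookup plane) is
possible but shortens the effective disector to 29 slabs, a systematic
−3.3%. No lateral guard zones are used.

**Tops vs. nucleoli.** Objects are counted at their first appearance
("tops"); the nucleus is the stained unit, so no sub-nuclear sampling site
is needed.

## Segmentation (automated workflow)

Stacks are converted to 8 bit by rescaling [global min, global max] to
[0, 255] (degenerate constant stacks map to 0 — an empty field is dark; the
integer path uses an exact lookup table), then flattened by
maximum-intensity projection. Pixels are classified by a random forest (100
trees, seeded, deterministic) over a fixed bank of 4 filter families ×
3 scales (Gaussian, difference-of-Gaussians, gradient magnitude, Laplacian
at σ ≈ 2.5, 5, 10 µm = 0.5/1/2 × the nominal 5-µm nucleus radius; scales
specified in µm and converted through the pixel size). Binary masks are
labelled with 8-connectivity; components smaller than the area of a disc of
half the nucleus radius (≈ 12 px at 1.3 µm/px) are discarded; a
distance-transform watershed seeded at maxima one nucleus radius apart can
split touching nuclei and is switched on by default above 500 cells/µl
(≥ 250k per 500-µl scaffold), where overlaps begin to matter.

Training scribbles matter more than the learner: background labels must
include pixels in the bright halo immediately outside nuclei (the package's
`sample_training_labels` draws half of each class from a ring around the
object boundary), otherwise any shallow classifier dilates objects
systematically. Ground truth for training and scoring a rendering is
defined as the half-maximum level set of the noiseless projection.

Otsu thresholding is retained as an untrained fallback; on sparse-foreground
fields it is markedly worse than the classifier and is not used by the
validation suite.

## Estimation

Per column, N̂ᵢ = cᵢ·V/v_col; the scaffold estimate is the mean of the nine
N̂ᵢ and the CV their n−1 sample SD over the mean (undefined when the
estimate is 0, or with a single column). Because all columns share one
volume, the mean-of-columns form coincides with the pooled form
Σc/(9·v_col)·V — both are exposed, the pooled one as a cross-check. The
estimate scales linearly in the counts.

## Statistics

For method comparison at one seeding density, the *theoretical value* (tv)
is the reference method's mean. Five per-observation measures: signed
deviation from tv (bias), |x − group mean| and its square (dispersion),
|x − tv| and its square (overall accuracy).

*Linear measures* are compared by heteroscedastic one-way GLS: with a
group-specific residual variance the REML solution is exactly the group
means and their n−1 sample variances, so the two-group contrast is the raw
mean difference with SE = √(s²ₐ/nₐ + s²ᵦ/nᵦ). Confidence intervals use a
*t* quantile with Satterthwaite degrees of freedom rather than a normal
quantile: at the study's group sizes (n = 4–25) the z-approximation
under-covers (≈ 93–94% in the suite's own coverage simulation) while the
Satterthwaite-t interval holds ≈ 95%. P-values come from a Monte-Carlo
permutation test on the Welch statistic (group labels permuted, default
5000 draws, p = (b+1)/(m+1) so p > 0; a pooled-variance statistic is
available by flag). A closed-form check against R's `nlme::gls` with a
per-group variance function is frozen into the tests.

*Squared measures* are fitted by a Gamma GLM with log link (statsmodels
IRLS); for the saturated two-group model the fitted effect equals
log(mean_a/mean_b) exactly, which doubles as the permutation statistic (no
refit per draw). Zero squared deviations are shifted by the smallest
positive value × 10⁻³ before the fit (Gamma support is positive); the
applied offset is reported. Residual normality is checked by Shapiro–Wilk
on standardized residuals plus Q-Q data; constant residuals raise rather
than returning an undefined p.

No multiple-comparison correction is applied; effects can be reported in
thousands of cells (linear measures only — Gamma effects are log ratios).

## Determinism and numerics

Every stochastic call takes one integer seed; the pipeline derives
per-stage child seeds from the run seed via `SeedSequence` and logs all of
them, so any output is regenerable from config + seed. Rendering
accumulates in float32 (values ≤ 2¹⁶, exactly representable); noise uses the
generator's float32 path. Permutation tests draw whole permutation matrices
at once; statistic ties are compared with a 10⁻¹² relative tolerance so
exact relabelings count as hits. Degenerate inputs are defined, not
accidental: constant stacks → zero image; zero estimate → CV reported as
missing; zero-variance groups → zero-width CI; all-equal permutation data →
p = 1.

## Validation problem sizes

The suite validates at sizes chosen to make Monte-Carlo error a small
fraction of each tolerance: 200 scaffolds for the sampling-CV band at the
lowest density, 500 scaffolds for estimator unbiasedness (<2%), one
9-column scaffold per density for disector/projection behaviour (overlap
losses there are deterministic given the points, so few columns suffice),
100 random layouts for exact frame additivity, 2000 replicates for
permutation-test size, 1000 for GLS coverage, and 6 training + 6 evaluation
fields and 54 automated columns for segmentation quality (pixel F1 pooled
over fields). `scripts/acceptance.py` re-simulates the sampling-CV
statistic (200 scaffolds) from a user-supplied seed.

## Known limitations

* The projection path undercounts as density grows (overlap merging); the
  disector resolves overlaps in z but still merges nuclei closer than the
  pixel grid can separate within one slab.
* The pixel classifier is trained and evaluated on the simulator's
  rendering model; real stacks will need their own scribbles and possibly a
  different filter-scale range.
* CV of the nine per-column estimates is interpreted as within-scaffold
  sampling noise; at the lowest density it is dominated by Poisson counting
  statistics (≈ 1/√28 ≈ 19%), which sits at the upper end of the expected
  9–20% band — denser scaffolds give proportionally smaller CVs.
* The Archimedes volume is quantized at instrument resolution; its ±10%
  relative error at 500 µl propagates multiplicatively into the estimate
  and is reported, not corrected.
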
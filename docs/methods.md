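# Methods

This note documents the models, parameters and numerical choices behind
`foldmetrics`, and what the synthetic validation does and does not show.

## Image model and extraction chain

**Total-variation denoising** (`preprocess`). The energy is the
anisotropy-free ROF form `F(u) = Σ|∇u| + (1/2λ)Σ(u−g)²` with a
forward-difference gradient and replicate (zero-flux) boundary, so the
last row/column contribute no gradient term. λ has grey-level units: it
is the coefficient that converts data misfit into the TV scale. λ = 0 is
special-cased to return the input bitwise. The minimiser is Chambolle's
dual projection with step τ = 1/4 (the empirical standard; the
convergence proof requires τ ≤ 1/8, and the accept-guard below makes the
larger step safe). Iterates are *accepted* only when the primal energy
does not increase; the best iterate is returned, so the recorded energy
trace is non-increasing by construction and the projection's
mean-preservation property carries to the output (|Δmean| < 1e-6 on
floats). Stopping: relative primal change < 1e-4 (default) or 200
iterations. Default λ = 12 grey levels — visible smoothing at 8-bit
scale; any analysis that depends on denoising should state its λ, and the
sensitivity of fold density to λ is deliberately surfaced as
configuration rather than resolved. Internal processing is float64;
conversion back to 8 bits (round half up) happens only at the
binarization input.

**Adaptive mean thresholding** (`binarize`). The threshold at pixel p is
the mean of the 35 × 35 replicate-padded neighbourhood (centre included)
plus an offset; comparison is strict, ties go black. For integer images
with integer offsets the comparison runs in exact integer arithmetic
(window sums by integral image), making the mask bit-reproducible with
no float tie ambiguity. Polarity is per-modality: the OCTA flow signal is
bright (`polarity='bright'`, offset +6); folds and vessel shadows on the
OCT slab are predominantly hyporeflective, so the OCT default is
`polarity='dark'` with offset −6 — algebraically identical to inverting
the image and applying the "local mean + 6" bright rule, which is the
only reading of the published threshold that does not turn a flat
background entirely white. The inequality direction is not recoverable
from the source text; it is configuration, not a guess baked in.

**Vessel subtraction and blob filtering.** The binarized OCTA mask is
first cleaned with the same <50-pixel blob rule (`octa_min_blob`,
default 50): vessels are large connected structures, so this removes
only noise speckle, which would otherwise punch holes into folds during
subtraction and fragment them below the size threshold. Subtraction is
saturating (white where OCT is white and the — optionally disk-dilated,
`dilate_radius` default 0 — vessel mask is black). Components with fewer
than 50 pixels are then discarded; exactly 50 is kept. Connectivity
default 8.

**Morphometry** (`fold_quant`). One 8-connected component = one fold,
ordered by topmost-then-leftmost pixel. The minimum-area rectangle is
computed by rotating calipers over the convex hull of the pixel centres
(some side of the optimal rectangle is collinear with a hull edge);
collinear components degenerate to width 0, single pixels to a point.
Side lengths are pixel-centre distances, so an N-pixel axis-aligned run
measures N−1; reported fold lengths/widths add 1 to restore pixel
counts. All rectangle geometry is converted from image (row, col) to the
bottom-left-origin, Y-up frame before slopes are computed. The diagonal
used for the gradient runs from the corner with minimal X+Y to its
opposite; the two diagonals of a rectangle have different slopes, and
for thin folds both fall on the same side of the ±1 boundary — near 45°
the tie rule takes over. A slope of exactly ±1 lies in neither of the
open classification intervals and is assigned to *horizontal* by default
(`tie` is configurable); ±∞ is vertical; a degenerate point rectangle
has undefined orientation and is classified horizontal with a warning.

## Synthetic data

**Image renderer.** Folds are cubic Bézier strokes: a chord of sampled
length, control points jittered perpendicular to it by
`curvature × length` (default 0.30), swept with a circular brush. Dull
folds depress intensity by 60 grey levels over the full stroke width;
sharp folds raise a ridge of one third the width by +60 flanked by
−30 bands — the two morphologies seen clinically, with the sharp form in
the minority (`sharp_fraction` 0.15). A branching random-walk vessel
tree covers `vessel_density` (default 8%) of the field; it is bright
(+80) in the OCTA and casts a matching −50 shadow in the OCT, which is
what the subtraction stage must remove. Noise is multiplicative speckle
(Gaussian in log intensity, σ/255) followed by additive Gaussian noise
(σ = 6 grey levels by default); truth masks are noise-free. Fold and
vessel masks may overlap; overlap pixels belong to both, and the
subtraction stage is what resolves them.

Stroke geometry vs measured morphometry: the study-scale morphometry
(mean rectangle length 27.5 px, width 13 px, ~53 folds, density ~8.3%)
is *mutually consistent only for thin curved strokes* — 53 solid
27.5 × 13 bars would cover ~16% of a 320² field. Renderer defaults
(chord 24 px, brush width 5 px, curvature 0.30) were chosen so that the
*measured* min-area-rect morphometry of rendered folds reproduces the
study values; `generate_dataset` maps sampled measured-scale length and
width back to stroke scale by the corresponding fixed ratios (24/27.5
and 5/13).

Per-fold ground-truth orientation is the class an ideal measurement
assigns to the isolated noise-free stroke (min-area rectangle + diagonal
rule); the geometric chord slope is stored separately (`chord_slope`).
For curved strokes the two can differ legitimately — recovery tests
therefore test the pipeline's robustness, not two competing definitions.

When `target_density_pct` is set, strokes are added (the final one
shortened as needed) until the truth density lies within 5% relative of
the target, stopping centred on the target; stagnation or exhaustion
raises a calibration error rather than silently under-delivering.

**Cohort sampler.** Every nonnegative clinical/fold quantity uses a
zero-truncated normal whose *parent* mean and SD are solved (Brent root
finding on the truncation coefficient of variation) so that the
*truncated* distribution matches the configured mean exactly and the SD
where feasible. The CV of a zero-truncated normal is bounded above by 1
(the exponential limit), and a few configured cells exceed that bound
(e.g. MH at month 6, 0.26 ± 0.36); for those the mean is matched exactly
and the SD capped at the achievable value — the alternative (parent
mean = configured mean) would bias the month-1 mean M-CHARTS score from
0.62 up to ~0.73. BCVA (logMAR, can be negative) uses a plain normal.
Fold counts are rounded to integers and `n_total` is defined as
`n_horizontal + n_vertical` (the configured total, 53.2, differs from
the component sum 53.1 by rounding in the source table).

Dependence is a Gaussian copula over 8 variable families × 3
timepoints. Within-family correlation across timepoints is `rho_time`
(default 0.6) and MV–MH share `rho_mvmh` (default 0.5) — the source
reports no joint structure, so both are explicit configuration. The two
calibrated associations (month-1 density with month-1 and month-6 mean
M-CHARTS, Spearman 0.419 and 0.515) are mapped to latent Pearson
correlations by r = 2 sin(πρ/6) and spread over the MV and MH components
scaled by √(2+2·rho_mvmh)/2 so that the latent correlation with the
(MV+MH) average equals the mapped value; because Spearman is invariant
under the monotone marginal transforms, the realized rank correlation of
the *average* approximates the target to well within ±0.02 at large n.
The assembled 24 × 24 matrix is checked for positive semidefiniteness
and sampling uses an eigendecomposition factor (stable at degenerate
boundaries); infeasible settings raise an error naming the calibrated
pairs.

## What the measurement can and cannot recover

The configured densities are themselves *measured* quantities of the
original acquisition chain, while the renderer calibrates the
*pre-subtraction truth* mask to them. Even a perfect binarizer, after
subtracting the true vessel mask and applying the strict 50-pixel rule,
retains only ~80–85% of truth fold pixels (vessel overlap plus fragment
loss). The per-image truth table therefore records
`ideal_measured_density_pct` — the density of
`fold_mask & ~vessel_mask` after the 50-px rule — and recovery is
assessed against that reference: the full pipeline tracks it to within a
few tenths of a percentage point at the study scale. Rank-based
quantities (the density–metamorphopsia Spearman) are insensitive to this
proportional attenuation and recover the configured association
directly. Clinical scores do not pass through the image chain at all.

What passing tests show: the extraction chain is pixel-faithful on
noise-free input, robust to the modelled speckle, and unbiased against
the ideal-measurement reference; the cohort generator reproduces the
configured first moments and rank correlations. What they do not show:
performance on real OCT speckle (which is correlated and
depth-dependent), real vessel-shadow morphology, segmentation-slab
errors, or fold shapes outside the Bézier family.

## Statistics

All tests wrap `scipy.stats` with the choices pinned: Wilcoxon
signed-rank uses Pratt zero handling, exact distribution for n < 25 when
there are no ties or zeros, otherwise the normal approximation with
continuity correction; Friedman uses the tie-corrected chi-square (the
all-identical-across-timepoints case is special-cased to statistic 0,
p 1, where the tie correction degenerates); post-hocs run only when
Friedman p < α and carry a Bonferroni factor of exactly 3 (capped at 1).
MV-vs-MH and vertical-vs-horizontal use Mann-Whitney U by default —
faithful to the published analysis despite the paired design — with a
paired Wilcoxon behind `paired_mv_mh=True`. Spearman uses average ranks;
p-values are exact (full permutation enumeration, chunked) for n ≤ 10
and the t approximation above; correlations of constant columns are
reported as NaN, never 0. The correlation table computes only the
upper-triangular (metric at t₁ × mean M-CHARTS at t₂ ≥ t₁) pairs.

## Problem sizes used in validation

Tabular cohort checks use 2000 eyes (sampling SE on the calibrated
Spearman ≈ 0.02); the rendered end-to-end check uses the study's 33 eyes
× 3 visits at 320 × 320 with 2·SE tolerances; oracle comparisons use
8×8 images for the TV minimum, 64×64 for thresholding, and 200 random
point sets for the rectangle fitter. These sizes were chosen to keep the
whole suite comfortably reproducible on a laptop while leaving sampling
error well below every tolerance asserted.
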
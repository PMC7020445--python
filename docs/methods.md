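# Methods

## Signal model

A cell's raw fluorescence is modelled as

    F(t) = F0 · (1 + d(t)) · (1 + b·t + c·t²) + ε(t),   ε ~ N(0, σ²)

where `d(t)` is the true ΔF/F₀ activity, the quadratic factor is
multiplicative photobleaching, and ε is additive acquisition noise.
Activity is a sum of transients: each event at time tₛ with amplitude A
contributes `A·exp(−(t − tₛ)/τ)` for t ≥ tₛ after a rise of
`rise_frames` frames (default 1, i.e. the rise is unresolved at the
10 s sampling interval). Event times are uniform over frames 2..n−2 with
a minimum separation of two frames so that consecutive peaks remain
resolvable; event counts are Poisson with a per-class rate; amplitudes
are normal per class, floored at a small positive value.

This form makes the bleach-correction stage exactly identifiable: the
correction fits the same quadratic family the generator uses, so
recovery failures indicate estimation error, not model mismatch.

## Synthetic populations

Four activity classes with control-condition defaults:

| class       | fraction | events / 600 s | amplitude (mean ± sd) |
|-------------|----------|----------------|-----------------------|
| hyperactive | 10%      | Poisson(12)    | 0.90 ± 0.15           |
| moderate    | 30%      | Poisson(3)     | 0.80 ± 0.15           |
| low         | 40%      | Poisson(3)     | 0.30 ± 0.08           |
| silent      | 20%      | 0              | —                     |

Other defaults: F₀ = 100 intensity units, noise σ = 2 (2% of baseline),
bleach (b, c) = (−4·10⁻⁴ s⁻¹, 10⁻⁷ s⁻²) (≈ 21% decay over 590 s),
τ = 15 s. The **hypoxia** preset shifts the mix to 25/40/25/10% and
raises the hyperactive amplitude mean to 1.2 — the direction of the
shift the analysis is meant to resolve, since no per-class prevalences
or amplitude statistics are available to estimate from.

Class proportions are interpreted as the exact composition of the
population (largest-remainder rounding, shuffled cell order) rather than
per-cell sampling probabilities. Replicate populations generated from
one configuration are therefore compositionally identical, which is the
premise of the donor-robustness analysis: differences between
same-configuration "donors" should reflect pipeline variability, not
compositional sampling noise. Per-cell i.i.d. class draws remain
available (`exact_composition=False`).

Two further presets serve as controlled benchmarks rather than realistic
mixtures. **detection**: every event amplitude ≥ 0.5 (mean 0.8 ± 0.08),
ΔF/F₀ noise 0.05, no bleaching — isolates the spike detector.
**separated**: Poisson event counts conditioned to each class's defining
band (> 6 / 1–6 / 1–6 / 0) with amplitude means 0.9/0.9/0.25 — classes
occupy disjoint feature regions, so the generating class is recoverable
by construction and misclassification measures pipeline error only.
With unconditioned Poisson counts a "low" cell genuinely emits 8 spikes
about 3% of the time; such a cell *is* hyperactive by the boundary
definition, and no classifier can (or should) recover its generating
label.

Movies place disc footprints of radius r at uniform random centres
rejected within `2r + margin` (default margin 3 px) of an existing
centre; every footprint pixel carries the cell's trace plus independent
pixel noise, background pixels a constant level plus noise. The
spike-free bleach-recovery benchmark uses noise σ = 0.5 (0.5% of
baseline) so the corrected-trace coefficient of variation reflects both
the bleach-fit residual and a realistic noise floor rather than being
dominated by either.

## Bleach correction

The trend is fitted per cell and divided out, anchored at t = 0:
`corrected(t) = F(t) · trend(0)/trend(t)`. Division (not subtraction)
preserves the scale-invariance of ΔF/F₀; subtraction is the fallback
only when a fitted trend is not strictly positive.

A plain least-squares fit over the whole trace is biased whenever
spiking is appreciable: positive transients pull the quadratic up
mid-recording and warp it at the edges, producing spurious baseline
excursions of 0.2–0.6 ΔF/F₀ in simulation — enough to corrupt spike
counts for over a third of cells. The default is therefore a two-stage
robust fit:

1. **Iterative peak clipping** (in the style of spectroscopy baseline
   estimators): after each quadratic fit, values more than one residual
   sd above the trend are clipped to trend + sd and the fit repeated
   (≤ 10 iterations). The clip is one-sided, so the symmetric noise
   floor — and hence the trend level — is essentially unbiased.
2. **Spike-masked refit**: transients are detected with the clipped
   trend, frames within (spike − 2 .. spike + 6) are masked (the decay
   tail is < 2% of amplitude after 6 frames at τ = 15 s), and the
   quadratic is refitted on the remaining baseline frames, provided at
   least 10 frames survive and the refit extrapolates positively.

The plain whole-trace fit remains available
(`DetectionParams(bleach_mask_spikes=False)`).

## Baseline and detection

F₀ is the 20th percentile of the corrected trace — robust as long as
transients occupy a minority of frames. Two numerical details matter:

- A raw order statistic of a noisy series under-estimates the baseline
  by ≈ 0.84 noise sd, inflating the ΔF/F₀ floor; the percentile is
  therefore taken on a 5-frame moving-average copy (the ΔF/F₀ numerator
  stays unsmoothed). `compute_dff` called directly defaults to the raw
  percentile so its closed-form behaviour is exact.
- For densely spiking cells (≳ 9 events, i.e. decay tails in most
  frames) the 20th percentile sits above true baseline and compresses
  amplitudes. This is inherent to quantile baselines at this sampling
  rate; amplitude features of hyperactive cells are conservative
  (compressed), never inflated.

Spikes are local maxima with ΔF/F₀ ≥ 0.2, prominence ≥ 0.15 and ≥ 2
frames separation (the larger peak wins conflicts). The thresholds are
configuration, logged on every run; with event amplitudes ≥ 0.5 and
noise sd 0.05 the detector recovers exact counts for ≈ 99% of cells,
and adding the generator's bleach trend changes a cell's count in < 1%
of cases.

## Segmentation

Pixel time series are centred and the economy SVD of the
(frames × pixels) matrix taken; the activity image is the pixelwise
root-sum-of-squares of the top-k singular-value-scaled loadings.
k defaults to min(10, components for 90% variance) — for fields with
many active cells k should be on the order of the expected cell count
(the acceptance benchmark uses k = 20 for 50 cells). The activity image
is thresholded by Otsu's method *in log space*: cell activity spans an
order of magnitude between dim and bright cells, and a linear-domain
Otsu splits bright cells from (dim cells + background) instead of cells
from background. Log-domain thresholding also makes the mask exactly
invariant to intensity rescaling. Connected components
(8-connectivity) within [20, 2000] px become ROIs, relabelled 1..n;
traces are footprint means per frame. A temporal-variance activity
image is available as a fallback (`segment_movie_variance`). No
watershed splitting: the synthetic fixtures are non-overlapping by
construction, and overlapping-cell demixing is out of scope.

## Clustering and classification

K-means (k = 4, k-means++, 50 restarts, seeded) on min–max scaled
(spike count, Ca²⁺max); unscaled features would let the ~10× larger
count dimension dominate. Centroids are mapped to classes through the
boundary rule (> 6 spikes ⇒ hyperactive; Ca²⁺max > 0.5 with ≥ 1 spike ⇒
moderate; 0 spikes ⇒ silent; else low). Because centroids have
fractional spike counts the two lower-activity clusters usually both
classify as "low"; the pair is split by centroid spike count (lower ⇒
silent). Data-driven boundaries are midpoints between the
moderate/hyperactive spike counts and the moderate/low Ca²⁺max, falling
back to the canonical 6 spikes / 0.5 ΔF/F₀ when a class is absent.

Subpopulation profiles draw 90-cell subsamples without replacement
(five repeats by default; an explicit sample size takes precedence over
the 60% fraction, resolving the 96-vs-90 ambiguity in favour of the
explicit sample size). Kruskal–Wallis with tie correction compares one
class percentage across conditions, treating subsample repeats as the
replication unit; p-values are asymptotic chi-square by default with a
seeded permutation mode (`p_method="permutation"`) for very small
samples, where the chi-square approximation is conservative.

## Companion assays

2^−ΔΔCt: per replicate ΔCt = Ct(target) − Ct(reference); ΔΔCt against
the mean control ΔCt; fold = 2^−ΔΔCt reported as mean ± SEM over
per-replicate folds (SEM on folds, not on ΔΔCt, matching the
mean-±-SEM-of-folds reporting convention; the log-domain alternative is
a one-line change on the per-replicate folds). Viability: percent =
100·(A − mean blank)/(mean control − mean blank) per well, then
mean ± SEM per dose; invariant to plate-reader gain/offset. Percentiles
throughout use linear interpolation between order statistics; box-plot
whiskers are the 10th/90th percentiles; significance is α = 0.05
everywhere.

## What the synthetic tests do and do not show

Passing recovery tests demonstrate that each stage inverts the
generator's model at realistic noise levels and sizes (hundreds of
cells, 60 frames) — they do not certify performance on real movies with
overlapping cells, motion, focus drift, non-quadratic bleaching, or
indicator saturation, none of which the generator emulates. Problem
sizes in the test suite and acceptance script (120–500 cells, one
256×256×60 movie, 20-seed robustness loops) were chosen so the full
validation runs in about a minute while keeping binomial noise on the
reported fractions near or below one percentage point.

## Known limitations

- Spike counting, not deconvolution: no sub-frame timing or rate
  estimation; at 10 s sampling, bursts within a frame merge.
- Quantile baselines compress amplitudes of densely spiking cells (see
  above).
- The activity-image segmentation cannot find silent cells (nothing
  fluctuates) and does not split touching cells.
- Kruskal–Wallis on subsample repeats treats draws from one population
  as replicates; with few conditions and five repeats the test resolves
  percentage shifts of roughly ten points, and its chi-square p is
  approximate at these sizes (the permutation mode is exact up to Monte
  Carlo error).
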
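# Methods

This note documents the models, algorithms and parameter choices in
`retrotrack`, what the simulator does and does not emulate, and the known
limitations. It is the place where genuinely open design decisions are
recorded.

## Scope and assumptions

The pipeline quantifies nuclear import of a fluorescently tagged,
cytoplasm-dominant shuttle protein from one *field*: `n` live frames of the
target-protein channel (frame 1 at time 0, one frame per
`frame_interval_min`, default 10 min) plus an end-point fixed pair — the
target-protein channel and a nuclear stain. Its core assumptions:

- cells undergo only minor morphological change during the experiment
  (cells that do move are *detected*, not tracked);
- the stage revisits the field accurately enough that a rigid integer
  translation aligns live and fixed images (no rotation, no deformation);
- the nuclear stain gives enough contrast that end-point segmentation is
  reliable even where the live channel is faint;
- before stimulation the cytoplasm is brighter than the nucleus (this is
  what makes the s.d.-vs-mean classifier work).

## Registration

Normalized cross-correlation over an exhaustive integer-shift grid
(`max_shift` = 20 px default; the worst stage-repositioning error we expect
at this magnification). The correlation at each candidate shift is computed
only over the mutually valid pixels, using the FFT masked-correlation
identity, so the result equals the brute-force definition up to rounding
(a brute-force oracle test asserts this). Near-equal peaks (relative
tolerance 1e-9) resolve to the smallest |dr| + |dc|, then row-major order,
making the operation deterministic. Candidate shifts whose overlap covers
less than 25% of the image are rejected; an image that is constant over
every admissible overlap raises an error (NCC undefined).

The chain registers frame *n* to the fixed target-protein image and each
earlier frame to the already-registered next frame, since adjacent frames
are most similar. Because every reference already sits in the fixed
coordinate system, each chained shift *is* that frame's cumulative shift;
the search radius must therefore cover the total drift, not the per-frame
step. Border pixels exposed by a shift are marked invalid and excluded
from every downstream statistic; validity only ever decreases along the
pipeline.

Registration uses the fixed target-protein channel as reference even though
fixation dims it unevenly — NCC is invariant to affine intensity changes
and tolerates smooth multiplicative fields well (the simulator's uneven
dimming stress-tests exactly this). No pre-processing precedes
correlation.

## Nuclear segmentation

Pipeline on the fixed nuclear-stain image:

1. Laplacian of Gaussian (σ = `log_sigma`, default 3 px — matched to the
   ~1.5–2 px edge width of a stained nucleus at 0.31 µm/px); contours are
   the 1-px zero-crossing rings on the negative (bright-interior) side,
   with crossings whose local LoG amplitude is below 4× the image median
   discarded as noise.
2. Contours are closed by a 1-px dilation, interiors flood-filled, and the
   closing compensated by a 1-px erosion.
3. Candidates are intersected with the Otsu foreground of the stain image
   — this is the combination operator chosen for "Otsu reduces the effect"
   of noise-driven false contours; the plain intersection keeps the
   operation monotone and order-independent.
4. Touching candidates are split by watershed on the negated distance
   transform, seeded at local maxima separated by ≥ `min_seed_distance`
   (default 5 px, about half a nuclear radius; smaller values oversplit).
5. Regions smaller than `min_area_fraction` (default 0.5) × the mean
   candidate area are removed. The mean is computed per field over all
   candidates after splitting — per-field adapts the cutoff to
   magnification and cell type. Note this rule intentionally removes any
   object below half the average nuclear area, including a genuinely tiny
   nucleus; it is a fragment filter, not a classifier.

Cytoplasm assignment works on the *first registered* frame (the masks live
in the fixed frame's coordinates, so the raw first frame would be
misaligned): Otsu foreground, seeded watershed with the nuclei as seeds on
a Gaussian-smoothed (σ = 2 px) negated intensity so ridges follow dim
inter-cell gaps, then per cell
`dilate(nucleus, d) ∩ territory ∩ foreground − nucleus`. Structuring
elements are Euclidean disks throughout. Erosion of the nuclear masks by
`e` before measurement strips boundary pixels contaminated by cytoplasmic
signal; regions eroded to extinction are flagged and excluded.

The package does not auto-select `d` and `e`; it exposes them and provides
the difference-variation machinery to compare settings, which is how such
settings are judged.

## The s.d.-vs-mean mask classifier

Per nucleus, the mean and population s.d. of the target-protein intensity
over the eroded mask are computed on the first registered frame — for
end-point masks the first frame shows the worst mask/nucleus match, so it
best represents the segmentation effect for the whole series; all frames
inherit the first-frame label.

The control population comes from stationary cells: fields imaged live
once and immediately fixed. (The fixed target-protein image itself cannot
serve as control because fixation dims the fluorophore unevenly.) The fit
is iteratively reweighted least squares with Tukey bisquare weights
(c = 4.685, the standard 95%-efficiency constant), scale re-estimated each
iteration as MAD/0.6745, run to a relative coefficient change of 1e-8 or
50 iterations; `statsmodels.RLM` provides the solver. The stored
`residual_scale` is the RMSE of the weighted residuals with n − 2 degrees
of freedom.

The "99.5% band" is a pointwise *prediction* band for a new observation,

  upper(x) = ŷ(x) + t(1 − α/2, n − 2) · s · √(1 + 1/n + (x − x̄)²/Sₓₓ),

not a mean-response confidence band — the latter shrinks like 1/√n and
would reject nearly every individual nucleus at large n. Only the upper
boundary gates the call: a low s.d. can only mean a cleaner-than-usual
mask, never a mismatch. Negative band values at small means are not
clamped (s.d. ≥ 0, so such points classify by the upper boundary as
everywhere else). The classification is exactly invariant under a common
affine intensity rescaling of control and test populations. Control
populations may be pooled across fields/experiments or kept per-experiment;
both are supported, and any n ≥ 3 is accepted.

Artificial mismatches for validation are produced by rigidly displacing
(translation + rotation about the centroid) real masks; the intersection
of a displaced mask with its original mimics a mask smaller than the real
nucleus.

Shape quality control computes nuclear perimeter, nuclear solidity, cell
perimeter and the per-nucleus mean/s.d. of both channels, and flags any
cell deviating from the population median by more than 3 robust standard
deviations (1.4826 × MAD) on any parameter.

## Translocation descriptors

- N:C ratio = (nuclear mean / cytoplasmic mean), normalized by the time-0
  ratio. The responder threshold, however, uses the *raw* ratio — the 95th
  percentile (linear interpolation between order statistics) of the
  pre-treatment population; normalizing first would erase the population
  spread the threshold relies on.
- NA = nuclear mean / same nucleus's time-0 mean. Needs no cytoplasmic
  mask, which is why it is the preferred kinetic descriptor.
- NI: ΔIᵢ = (Iᵢ − Iᵢ₋₁)/I₁, i = 2..n, where Iᵢ is the per-cell nuclear
  mean over the eroded mask (the same quantity NA uses). The telescoping
  identity Σᵢ ΔIᵢ = NA − 1 holds exactly. For the time of maximum import
  speed NI is re-evaluated on a 20-min grid (NI is noisier than NA);
  the per-frame 10-min NI is also available on every trace. The returned
  time labels the end of the winning interval, with near-ties (relative
  1e-9) resolving to the earliest interval.
- Difference variation |V₁ − V₂|/(V₁ + V₂) ∈ [0, 1] compares two mask
  settings; all three descriptors are invariant under a global intensity
  gain.

Population summaries report median, 5th/95th percentiles, mean and s.d.
per frame, stratified into all / matched-only / mismatched-or-false cells.
Spearman rank correlation, the paired Wilcoxon signed-rank test and the
Jarque–Bera normality test are provided as thin wrappers over scipy with
their standard definitions.

## The simulator

`simgen` renders the full experimental design: 12-bit 512×672 frames,
13 frames at 10-min intervals, tens of cells per field. What it emulates,
with defaults chosen as realistic study conditions:

- **Geometry**: non-overlapping elliptical cells (rejection-sampled
  placement), nuclear radius 10 ± 1 px (~10% CV — typical nuclear-size
  dispersion at 0.31 µm/px; it also keeps real nuclei above the
  segmentation fragment cutoff, as they are in real fields), cytoplasmic
  radius 18 ± 2 px with a floor of 1.8× the nuclear radius.
- **Expression**: per-cell log-normal (median 600 AU, σ_log 0.4),
  emulating transient transfection. Baseline N:C ratio 0.6
  (cytoplasm-dominant).
- **Kinetics**: responders (default 80%) follow a delayed logistic
  NA(t) = 1 + (F − 1)·(σ(k(t − lag − t_half)) − σ₀)/(1 − σ₀), normalized
  to exactly 1 at t = 0 — the minimal curve with a lag, an acceleration to
  maximum speed and a plateau. Defaults: lag 20 ± 5 min, inflection at
  lag + 40 ± 10 min, plateau fold 3 ± 0.5, rate 0.15 min⁻¹. Cytoplasm is
  depleted conservatively (total cell fluorescence constant), with each
  cell's fold capped so its cytoplasm keeps ≥ 10% of baseline.
- **Cytoplasm structure**: brighter near the nucleus (gradient 0.3, cells
  are thicker there), and depletion weighted toward the perinuclear region
  (tilt 0.8) so the cytoplasmic profile changes shape over time. Without
  this the profile would be separable in time and the time-0 normalization
  of the N:C ratio would cancel mask dependence exactly, making
  mask-setting comparisons vacuous — real cytoplasm has time-varying
  spatial structure.
- **Motion**: 3.5% of cells move (1.5 px/frame in a random direction,
  2°/frame rotation); optional global stage drift, plus an optional extra
  shift between the last frame and fixed imaging.
- **Fixation**: the fixed target-protein image is the end-point render
  times a smooth random multiplicative field (mean 0.7, spatial s.d. 0.15,
  Gaussian smoothing 48 px) — the uneven dimming that motivates using live
  frames as the movement control. The nuclear stain renders nuclei at
  2000 AU on a 50 AU background.
- **Noise**: additive Gaussian (s.d. 8 AU) plus a signal-proportional
  component (8% of the pixel value), clipped to [0, 4095]. Photobleaching
  is off by default (control experiments show no significant fluorescence
  variation over 2 h at these exposures).

Ground truth includes label images at the fixed geometry, noise-free
per-cell mean trajectories, true stage shifts, and all per-cell parameters.
Output is bit-identical for a given seed.

Not emulated: PSF/optics, mitosis, cell crowding/contact, autofluorescence
structure, shape change other than rigid motion, and intra-nuclear texture
(nuclei are uniform, so mask-shrinkage invariance of NA is exact by
construction rather than approximate as in real data). Consequently,
passing tests show the *pipeline logic* is correct under the stated noise
and motion models; they do not certify performance on crowded or
low-contrast real fields.

## Numerical choices and degenerate inputs

- Registration tie-break and overlap floor: see above; FFT overlap counts
  are rounded to integers before use.
- Otsu requires ≥ 2 distinct valid intensities; constant images raise.
- Watershed marker ordering and dense relabelling are deterministic (scan
  order), so segmentation is reproducible bit-for-bit.
- Regions with < 2 valid pixels yield no statistics and are flagged;
  population s.d. uses ddof = 0.
- Cells with non-positive baseline nuclear or cytoplasmic means cannot be
  normalized and are flagged invalid rather than propagating NaNs
  silently.
- Percentiles use linear interpolation between order statistics.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the pipeline end-to-end on
simulated fields. Sizes were chosen to exercise every stage at
full default geometry where the check depends on it: 50 random shifts in
[−15, 15]² for registration recovery (256×336 frames); 30-cell fields at
512×672 for segmentation IoU; a 500-cell pooled control (5 × 100-cell
fields) for the classifier with 100-cell held-out stationary and
shifted-mask populations; ~210 cells over three fields for the
difference-variation comparison; 25 noise-free responders for kinetic
recovery. All randomness is seeded; the acceptance script derives every
sub-seed from its `--seed` argument.

## Known limitations

- Integer-pixel, translation-only registration: subpixel drift blurs
  nothing (no resampling) but accumulates as ±0.5 px mask offset; rotation
  of the stage between live and fixed imaging is not corrected.
- Mask identity is fixed by the end-point segmentation — that is the
  method's point, but it means a cell that moved early contributes a
  stale mask for the whole series (it is flagged, not fixed).
- The classifier assumes cytoplasm-dominant baseline fluorescence; for a
  nucleus-dominant protein the s.d. inflation argument inverts.
- The 95th-percentile responder threshold is unstable below ~20
  pre-treatment cells (a warning is raised).
- `d`, `e` selection is manual; the difference-variation tool quantifies
  the consequence of a choice but does not optimize it.
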
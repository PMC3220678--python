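# retrotrack

Retrospective, automated quantification of nuclear–cytoplasmic translocation
in time-lapse fluorescence microscopy.

## The problem

Many signalling proteins — STAT1/3, NF-κB p65, Smads, the glucocorticoid
receptor — sit mostly in the cytoplasm and move into the nucleus on
stimulation. Measuring that movement per cell in live imaging is hard
precisely when it matters: before and during translocation the nuclear
boundary is faint in the target-protein channel, expression varies wildly
between transiently transfected cells, and most segmentation tools only work
well on fixed, stained material.

The *retrospective* strategy sidesteps live segmentation entirely: image the
field every 10 min, then fix the cells at the end of the experiment and
stain the nuclei with a DNA dye (e.g. Hoechst). The high-contrast end-point
nuclear image is segmented once, and the resulting masks are propagated
*backwards* through the live series after registering every frame to the
fixed reference. The price is that cells which moved or changed shape
during the experiment carry a stale mask; the method therefore includes a
statistical detector for exactly those cells.

`retrotrack` implements the full pipeline for one *field* (a live frame
series plus a fixed target-protein/nuclear-stain image pair), together with
a ground-truthed simulator of the whole experiment, so every stage is
testable without microscope data. It is aimed at image-analysis and
systems-biology groups quantifying shuttle-protein kinetics per cell.

## Method

1. **Registration** (`registration`): integer-pixel translation by
   normalized cross-correlation, evaluated only over mutually valid pixels.
   The last live frame is registered to the fixed target-protein image;
   each earlier frame is registered to the already-registered next frame
   (adjacent frames are most similar). Borders exposed by shifts are
   tracked in a validity mask, never filled with fake intensities.
2. **Segmentation** (`segmentation`): nuclei from the fixed nuclear stain
   by Laplacian-of-Gaussian contour detection + flood fill, intersected
   with the Otsu foreground, split by distance-transform watershed, with
   fragments below half the mean candidate area removed. Cytoplasm from
   the first registered frame (strongest cytoplasmic signal): Otsu
   foreground partitioned by seeded watershed, each cell's cytoplasm being
   the territory within a disk dilation (radius `d` ∈ [6, 20] px) of its
   nucleus. For measurement the nuclear masks are eroded by `e` ∈ [2, 6] px
   to avoid cross-contamination at the boundary. Cells touching any image
   edge or registration border are excluded.
3. **Motile/mis-segmented cell detection** (`mask_qc`): for a
   cytoplasm-dominant protein, a mask that slipped onto cytoplasm mixes two
   intensity populations, inflating the pixel s.d. far more than the mean.
   Across stationary control cells (imaged live once, then fixed) the
   per-nucleus s.d. is nearly linear in the mean; a robust IRLS line
   (Tukey bisquare, c = 4.685) with a pointwise prediction band

   sd ≤ slope·mean + intercept + t₁₋α/₂,ₙ₋₂ · s · √(1 + 1/n + (mean − x̄)²/Sₓₓ)

   classifies first-frame (mean, s.d.) pairs: inside/below the upper band →
   *matched*, above → *mismatched or false* (α = 0.005, a 99.5% band).
4. **Quantification** (`quantify`): per cell and frame,
   N:C ratio (nuclear/cytoplasmic mean, normalized to 1 at time 0),
   NA = nuclear mean / its time-0 mean, and the import-speed proxy
   NI: ΔIᵢ = (Iᵢ − Iᵢ₋₁)/I₁. Responders are cells whose end-point raw N:C
   ratio exceeds the pre-treatment 95th percentile; the time of maximum
   import speed is the argmax of NI on a 20-min grid. Two mask settings can
   be compared via the difference variation |V₁ − V₂|/(V₁ + V₂).
5. **Simulation** (`simgen`): renders the whole experiment — elliptical
   cells with log-normal expression, delayed-logistic import kinetics with
   conservative cytoplasm depletion, motile cells, stage drift, uneven
   fixation dimming and signal-dependent noise — with full ground truth.

## Worked example

```python
import numpy as np
from retrotrack import PipelineConfig, analyze_field, control_fit_from_field, time_to_max_speed
from retrotrack.quantify import call_responders
from retrotrack.simgen import SimConfig, simulate_control, simulate_field

config = PipelineConfig(d=8, e=3, alpha=0.005)

# stationary-cell control: one live frame, then fixation
control_field, _ = simulate_control(SimConfig(n_cells=60, seed=1, mover_fraction=0.0))
fit = control_fit_from_field(control_field, config)
print(f"control fit: sd = {fit.slope:.4f} * mean + {fit.intercept:.2f}  (n={fit.n}, RMSE={fit.residual_scale:.3f})")

# a stimulated field: 13 frames, 10 min apart
field, truth = simulate_field(SimConfig(n_cells=40, seed=2))
result = analyze_field(field, config, control_fit=fit)
classes = result.class_of()
print(f"cells analysed: {len(classes)}, matched masks: {sum(v == 'matched' for v in classes.values())}")

valid = [t for t in result.traces if t.valid]
pre = np.array([t.raw_nc[0] for t in valid])
post = np.array([t.raw_nc[-1] for t in valid])
responders, threshold = call_responders(pre, post)
print(f"responder threshold (raw N:C 95th pct): {threshold:.4f}; responders: {responders.sum()}/{len(valid)}")

resp = [t for t, r in zip(valid, responders) if r]
print(f"median plateau NA of responders: {np.median([t.na[-1] for t in resp]):.3f}")
print(f"median time to max import speed: {np.median([time_to_max_speed(t) for t in resp]):.0f} min")
```

Output:

```
control fit: sd = 0.0728 * mean + 3.16  (n=60, RMSE=1.087)
cells analysed: 40, matched masks: 37
responder threshold (raw N:C 95th pct): 0.6010; responders: 31/38
median plateau NA of responders: 3.005
median time to max import speed: 60 min
```

The control fit is the s.d.-vs-mean line of stationary nuclei; 37/40 masks
in the stimulated field classify as matched (the simulator plants ~3.5%
movers). Before stimulation the cytoplasm is brighter than the nucleus, so
the raw N:C threshold sits near the baseline ratio of 0.6; the simulated
responders (80% of cells) import to a 3-fold plateau (recovered 3.005) with
maximum speed around the configured 60-min inflection.

The same pipeline is scriptable from the shell:

```
retrotrack simulate --seed 3 --n-cells 15 --out-dir field/
retrotrack register --field field/ --out-dir registered/
retrotrack quantify --field field/ --control ctrl/ --out-dir results/
```

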
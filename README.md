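# pcflow

Semi-automatic vessel segmentation and blood-flow quantification for
time-resolved 2D phase-contrast MR (PC-MR), aimed at researchers who
measure aortic / pulmonary flow volumes, cardiac index and Qp/Qs shunt
ratios and want contours in every cardiac phase from a single manual
delineation.

## The method

A PC-MR series is a paired magnitude/phase stack over one cardiac
cycle; phase ±π encodes through-plane velocity ±VENC (cm/s). Flow
through a lumen contour C in frame t is

    Q(t) = Σ_{pixels ∈ C} v(x, y, t) · ΔA        [ml/s]

and the net flow volume is the Riemann sum `V = Σ_t Q(t)·Δt`. The hard
part is obtaining C in every frame when lumen/background contrast
collapses during diastole. Starting from one manual contour, `pcflow`:

1. tracks rigid in-plane motion between adjacent magnitude frames
   (normalized cross-correlation, integer shifts);
2. orders frames by the median velocity inside the motion-tracked seed
   (exact 1-D 2-means split into high/low-velocity classes), processing
   the high-velocity — high-contrast — interval first and initializing
   every frame from an already-processed temporal neighbour;
3. refines each contour with an edge-guided active contour (explicit-
   Euler snake on the magnitude edge map with tension and rigidity
   forces);
4. projects the result onto a PCA shape model learned from reference
   delineations — radial parameterization at 48 equiangular rays,
   scale/translation normalized out, mode coefficients clipped at
   ±3 SD — so shape stays anatomical while position and size remain
   free;
5. rescales all contours by a fixed, numerically optimized diameter
   factor compensating the inward bias of the edge detector.

Flow quantification applies a linear (planar) background-phase
correction fitted to static tissue before the flow sums. A synthetic
pulsatile-phantom generator with closed-form flow ground truth
(parabolic profile: `Q = v_peak/2 · πR²`) supports end-to-end
validation, including the diastolic contrast drop and adjacent bright
anatomy that make unconstrained snakes fail. See `docs/methods.md` for
the full model description and design rationale.

## Worked example

```python
import numpy as np
from pcflow import (default_phantom_spec, dice_per_phase, fit_shape_model,
                    generate_phantom_series, generate_training_set,
                    quantify_flow, segment_series)

model = fit_shape_model(generate_training_set(12, seed=1001),
                        vessel_label="aorta")
series, truth, _, true_volume = generate_phantom_series(
    default_phantom_spec(seed=1))
seed = truth.contours[6]                      # manual contour at 20% RR
result = segment_series(series, seed, model=model)
flow = quantify_flow(series, result, bsa=1.9)
d = dice_per_phase(result, truth, series.shape)
print(f"net volume {flow.net_volume:.1f} ml (truth {true_volume:.1f} ml)")
print(f"cardiac index {flow.cardiac_index:.2f} l/min/m2 at {flow.heart_rate:.0f} bpm")
print(f"median Dice {np.median(d):.3f}, processing started at phase {result.processing_order[0]}")
```

prints

```
net volume 66.0 ml (truth 66.1 ml)
cardiac index 2.31 l/min/m2 at 67 bpm
median Dice 0.946, processing started at phase 6
```

i.e. the pipeline recovers the phantom's analytic stroke volume within
0.1 ml, the derived cardiac index for a 1.9 m² subject at the phantom's
67 bpm, and a median per-frame Dice overlap of 0.946 against the true
lumen; processing starts at the seed frame because it lies in the
high-velocity class.

The same pipeline is available from the shell:

```
pcflow simulate --seed 1 --out phantom/
pcflow train-shape-model --synthetic-subjects 12 --seed 1001 --out model.npz
pcflow segment --series phantom/series.npz --seed-contour phantom/truth.json \
               --seed-phase 6 --model model.npz --out seg.json
pcflow quantify --series phantom/series.npz --contours seg.json --bsa 1.9 --out flow.csv
pcflow evaluate --pred seg.json --truth phantom/truth.json --out stats.json
pcflow run-all --seed 1 --out report/
```

`pcflow run-all --seed 1 --out report/` sweeps five phantom stroke
volumes (≈12–90 ml), segments each from a seed at 20% of the RR
interval and prints

```
volume bias -0.23 ml, SD 0.18 ml, median Dice 0.955; report in report/report.json
```

Algorithm parameters can be overridden with a YAML file mirroring
`AlgorithmParams` (see `configs/default_params.yaml`) via `--config`.
Real data are read from DICOM directories (common two-series
magnitude/phase layout) or the package's `.npz` array container.

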
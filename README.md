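# spiralad

Screening for early-stage Alzheimer's disease (AD) from the *dynamics* of a
drawn Archimedes spiral. A digitizing tablet records the pen at 125 Hz —
position *x(t), y(t)*, pressure *p(t)*, and the barrel angles azimuth
*Az(t)* and altitude *Alt(t)* — including the in-air ("pen-up") trajectory
near the surface. A scanned drawing keeps only the shape; this package keeps
the gesture.

The package is aimed at researchers in digital biomarkers and handwriting
analysis who want a complete, reproducible implementation of the
trajectory-image + transfer-learning methodology, plus a synthetic cohort
generator to develop against when clinical recordings cannot be shared.

## Method

1. **Hybrid trajectory images.** For each dynamic parameter
   d ∈ {pressure, altitude, velocity, acceleration}, its per-sample value is
   min–max normalized over the whole study population,
   v̂ = (d − d_min)/(d_max − d_min), and mapped pointwise onto the drawn
   trajectory as a gray level g = round(255·(1 − v̂)) — low values white,
   high values black. Velocity and acceleration are finite differences of
   position: v = √(v_x² + v_y²) with v_x = Δx/Δt, and a = √(a_x² + a_y²)
   with a_x = Δv_x/Δt. Pressure views render pen-down samples only (in-air
   pressure is identically zero), so the trace "breaks" at pen lifts;
   velocity, acceleration and altitude views render the whole gesture,
   bridging lifts.
2. **Off-the-shelf deep features.** Each image is fed to a fixed
   AlexNet-architecture network and the activation at one tap point —
   Conv1…Conv5 (after ReLU, and after max-pooling where pooling follows) or
   fc7 — is flattened into a descriptor (e.g. 9216 dims at Conv5, 4096 at
   fc7). The network is never trained here. Because no pretrained parameter
   set ships with the package, the default weights are seeded He-initialized
   random projections (`weights_mode="random_seeded"`), which are
   deterministic and preserve gross image structure; requesting
   `"pretrained"` raises an error explaining the fallback.
3. **SVM experts under balanced resampling.** With 45 healthy controls (HC)
   and 30 AD subjects (one spiral each), each of 10 repetitions samples 30
   of the 45 HC, trains an RBF-SVM on 20 HC + 20 AD, and tests on the
   held-out 10 + 10. (C, γ) come from a grid search with stratified 5-fold
   cross-validation on the training split; features are z-scored with
   train-only statistics. Reported: mean ± std over repetitions of accuracy,
   sensitivity (% AD correct; AD is the positive class) and specificity
   (% HC correct).
4. **Fusion.** Decision fusion takes the majority vote of an odd number of
   experts (e.g. pressure/altitude/velocity at one layer, or nine experts
   across three layers). Low-level fusion instead stacks three hybrid views
   into the three input channels of one image and trains a single expert.

Because the original clinical recordings are private, the package includes a
synthetic spiral generator: Ornstein–Uhlenbeck angular speed, 4–7 Hz radial
tremor, AR(1) pressure and altitude noise, and Poisson-count in-air
excursions. An effect size ε ∈ [0, 1] interpolates the AD generative profile
from identical-to-HC (ε = 0) to fully contrasted (ε = 1: lighter and more
variable pressure, more tremor and speed jitter, more in-air excursions,
more variable pen altitude).

## Worked example

```sh
spiralad run --config cfg.yaml --seed 7 --weights random --out runs/demo
```

with `cfg.yaml`:

```yaml
cohort: {n_hc: 45, n_ad: 30, effect_size: 1.0}
views: [pressure, altitude, velocity]
layers: [Conv3]
fusion:
  - mode: single_layer_multi_view
    experts: [[pressure, Conv3], [altitude, Conv3], [velocity, Conv3]]
```

prints:

```
wrote 75 streams to runs/demo/streams
wrote 225 images to runs/demo/images
expert altitude/Conv3: acc 100.0±0.0  sens 100.0±0.0  spec 100.0±0.0
expert pressure/Conv3: acc 83.5±9.0  sens 94.0±18.0  spec 73.0±17.9
expert velocity/Conv3: acc 95.5±4.7  sens 100.0±0.0  spec 91.0±9.4
fusion single_layer_multi_view: acc 97.5±2.5  sens 100.0±0.0  spec 95.0±5.0
```

Reading: 75 synthetic subjects were generated at full effect size, rendered
in three hybrid views (225 PNGs), and each view's Conv3 descriptors trained
one SVM expert under the 10-repetition protocol. On this cohort the altitude
expert separates the classes perfectly, the pressure expert reaches
83.5% mean accuracy, and the three-expert majority vote reaches 97.5% mean
accuracy with 100% sensitivity (every AD test subject classified AD in every
repetition) and 95% specificity. `runs/demo/summary.csv` holds these rows
and `runs/demo/results.csv` the per-repetition confusion counts
(`spiralad report --out runs/demo` pretty-prints the summary). Synthetic
cohorts at full effect are deliberately easy; the numbers characterize the
pipeline, not clinical performance.

The same pipeline is available as a library:

```python
import spiralad as sp

cohort = sp.generate_cohort(sp.CohortConfig(effect_size=1.0, seed=7))
images, stats = sp.render_views(cohort, ("pressure", "altitude", "velocity"))
store = sp.FeatureStore({s.subject_id: s.label for s in cohort})
for view, imgs in images.items():
    for img in imgs.values():
        store.add([sp.extract_features(img, "Conv3", sp.ExtractorConfig(seed=7))])
plan = sp.make_sampling_plan(master_seed=7)
scheme = sp.FusionScheme(
    (("pressure", "Conv3"), ("altitude", "Conv3"), ("velocity", "Conv3")),
    "single_layer_multi_view",
)
print(sp.run_decision_fusion(scheme, plan, store).summary())
```

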
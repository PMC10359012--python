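# mousemime

Classification and interpretation of emotional facial expressions in
head-fixed mice, rebuilt as a tested, fully synthetic-reproducible
pipeline.

Laboratory mice move their ears, eyes, mouth and jaw in
stimulus-specific ways: a noxious tail pinch evokes a crumpled ear and
an open mouth, pleasant brushing a crumpled ear, a bent jawline and a
deformed eye, while the neutral face keeps a flat ear, a closed mouth
and a straight jawline. This package implements the full analysis chain
that turns lateral face images into a three-state emotion classifier and
then verifies *what* the classifier looked at:

1. **Synthetic face benchmark** — a deformable lateral-head generator
   with per-part ground-truth masks and known generative parameters,
   standing in for undeposited mouse videos. Nuisance factors (head
   size/position, brightness, background) are drawn i.i.d. across states
   so no shortcut features exist.
2. **Preprocessing** — subject masking, compositing onto the uniform
   background color RGB **[200, 167, 122]**, resize to **227 × 227**.
3. **Dataset building** — per-class down-sampling to the minimum class
   count (the emulated acquisition yields 73 598 / 3 099 / 3 999 frames,
   balanced to 3 099), a stratified **64 : 16 : 20**
   train/validation/test hold-out split, and online augmentation
   (random up–down flip, random translation up to 30 px at net scale).
4. **Fire-module CNN** — a SqueezeNet-v1.1-style classifier (1×1
   "squeeze" → parallel 1×1/3×3 "expand" convolutions) written in
   NumPy with hand-derived backprop, trained by mini-batch SGD with
   momentum on cross-entropy for **110 iterations** with validation
   every 10. Gradients are verified against central finite differences.
5. **Grad-CAM** — channel weights `α_c = mean ∂y/∂A_c`, saliency
   `ReLU(Σ α_c A_c)`, max-normalized and upsampled; the top-five-scoring
   test images per state are overlaid. An independent finite-difference
   Grad-CAM oracle validates the backprop route.
6. **Morphometry** — the ten facial parameters (mouth opening, jaw
   angle, ear/eye angle, eccentricity `√(1−(b/a)²)` and Ramanujan-II
   perimeter of moment-fitted ellipses, ear-to-eye angle and distance)
   measured from part masks and landmarks.
7. **State space** — z-scoring `(X − X_mean)/X_SD`, 3-component PCA,
   neutral ±2 SD coverage fractions, and silhouette-based separation
   scores.

## Worked example

```python
from mousemime.pipeline import run_synthetic_experiment

res = run_synthetic_experiment(n_per_state=300, seed=1)
print(res.cm.to_dataframe())
for state, m in res.metrics["per_class"].items():
    print(f"{state:11s} sensitivity {m['sensitivity']:5.1f}%"
          f"  specificity {m['specificity']:5.1f}%")
```

prints (≈75 s on one CPU core):

```
            neutral  tail_pinch  brushing
neutral          58           2         0
tail_pinch        8          49         3
brushing          1           1        58
neutral     sensitivity  96.7%  specificity  92.5%
tail_pinch  sensitivity  81.7%  specificity  97.5%
brushing    sensitivity  96.7%  specificity  97.5%
```

Rows are true states, columns predicted states of the 180 held-out test
frames; sensitivity is the per-state recall, specificity the one-vs-rest
true-negative rate. The same run exposes the trained model for saliency
(`mousemime.gradcam`) and the records for morphometry/PCA
(`mousemime.pipeline.morphometry_statespace`).

The command-line interface mirrors the library:

```bash
mousemime synth --n 300 --seed 1 --out data/ --profile default
mousemime run --seed 1 --n 300 --out runs/demo   # full pipeline
```

`runs/demo` then contains the split manifest, training history, weight
archive, confusion matrix and metrics, Grad-CAM overlays, the
ten-parameter morphometry table, PC scores/loadings and a 3-D state-space
scatter, plus `manifest.json` and `repro.json`.

## Layout

```
src/mousemime/
  synthetic_faces.py   generator (FaceParams, SceneConfig, render)
  preprocess.py        detect_subject / composite / resize_for_net
  dataset_builder.py   balance_classes / split_holdout / augment
  nn.py                fire-module CNN, SGD-momentum training loop
  gradcam.py           saliency maps, finite-difference oracle, overlays
  morphometry.py       the ten facial parameters
  statespace.py        z-score, PCA, ±2 SD coverage, silhouette
  evaluation.py        confusion matrix, sensitivity/specificity
  pipeline.py          orchestration and run directories
  cli.py               `mousemime` subcommands
docs/methods.md        model, parameters, design choices, limitations
```
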
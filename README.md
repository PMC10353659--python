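# gfseg

Synthetic crop-canopy imaging and green-fraction segmentation evaluation.

The green fraction (GF) — the fraction of green vegetation visible in a
given viewing direction — is a standard canopy trait estimated from RGB
images by segmenting green-vegetation pixels and computing
GF = green pixels / total pixels. Training and validating such segmenters
is bottlenecked by pixel-accurate annotation. `gfseg` attacks this with
simulation: it procedurally generates 3D rice and wheat canopy scenes,
renders them to images with pixel-perfect green-vegetation masks, builds
tiled segmentation datasets, runs a classical excess-green baseline (or
any external deep segmenter through an adapter contract), and evaluates
results at the pixel scale (confusion proportions, Accuracy, F1), the
image scale (GF, R², RMSE), and per pixel (error maps, lightness/greenness
densities). It is aimed at phenotyping researchers who want controlled,
perfectly labeled test beds for vegetation segmentation methods.

## Core quantities

With green vegetation as the positive class and TP/TN/FP/FN the confusion
proportions over all pixels:

- Accuracy = (TP + TN) / (TP + TN + FP + FN), F1 = 2·TP / (2·TP + FP + FN)
- GF = (green pixels) / (total pixels); predicted vs reference GF compared
  by R² = 1 − Σ(fᵢ − yᵢ)² / Σ(yᵢ − ȳ)² and RMSE = √(Σ(fᵢ − yᵢ)²/n)
- Domain gap between image sets: mean over random cross-set pairs of the
  normalized Euclidean distance √(mean(((xᵢ − yᵢ)/255)²)) on digital numbers
- Greenness: ExG = 2G − R − B on raw 8-bit values; brightness: CIELAB L*

Canopies are built from a ~13-dimensional parameter space (plant density,
row spacing, organ counts, leaf length/width/inclination/curvature,
height, color), sampled by Latin-hypercube sampling and replicated over
growth stages; scenes render through a pinhole camera with z-buffer
rasterization, and the mask is decided per pixel by majority vote on a
4×4 subpixel coverage grid from the same geometry pass — so labels are
exact and independent of illumination.

## Worked example

```python
from gfseg import canopy_sim, render, segment, evaluate

space = canopy_sim.default_space("wheat", n_stages=4)
points = canopy_sim.sample_parameter_space(space, n=4, seed=7)
p = canopy_sim.expand_stages(points)[13]           # one point, stage 2
scene = canopy_sim.build_canopy(p, plot_extent=(0.7, 0.7))

camera = render.CameraConfig(height=1.0, fov=40, inclination=0, resolution=512)
light = render.LightConfig(condition="sunny", diffuse_fraction=0.45, shadows=False)
sample = render.render_sample(scene, camera, light, seed=7, params=p)

pred = segment.segment_exg_otsu(sample.rgb)
c = evaluate.confusion_counts(pred, sample.mask)
acc, f1 = evaluate.pixel_metrics(c)
print(f"GF(truth)={evaluate.green_fraction(sample.mask):.3f} "
      f"GF(pred)={evaluate.green_fraction(pred):.3f} acc={acc:.3f} f1={f1:.3f}")
```

prints

```
GF(truth)=0.093 GF(pred)=0.096 acc=0.995 f1=0.976
```

i.e. this stage-2 canopy covers 9.3% of the image, the excess-green
baseline slightly over-segments it (9.6%), and against the simulator's
perfect mask it reaches pixel accuracy 0.995 and F1 0.976.

The same pipeline is available from a shell:

```sh
gfseg simulate --crop wheat --n-samples 4 --n-stages 4 --out run/ --seed 7
gfseg tile     --images run/images --out run/
gfseg split    --tiles run/tiles --out run/
gfseg segment  --manifest run/manifest.json --out run/
gfseg evaluate --manifest run/manifest.json --pred-dir run/predictions --out run/metrics
```

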
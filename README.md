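# granuleseg

Automated segmentation and morphometry of insulin secretory granules (large
dense-core vesicles) in 2-D electron micrographs of pancreatic beta cells.

Under the electron microscope an insulin granule is a roughly spherical
organelle, 100–800 nm in diameter, with an electron-dense core separated
from the limiting membrane by a bright halo.  Counting and measuring
thousands of them by hand across serial FIB-SEM sections is impractical, and
naive segmenters confuse dark nuclear regions with granule cores.
`granuleseg` is for microscopists and image analysts who need per-granule
numbers — density per μm² of cytoplasm, radius and dense-core radius
distributions, round coefficient, distance to the plasma membrane — from
8-bit grayscale micrographs.

The pipeline: **histogram equalization** → **MFCN semantic segmentation** →
**watershed instance splitting** → **morphometry**, with evaluation metrics
(pixel accuracy, mean accuracy, mean IU, and object-level TP/FP/FN with
precision) and a seeded synthetic-micrograph generator that provides full
ground truth for testing and calibration.

## The model

The MFCN (multi-branch fully convolutional network) is a 2-class segmenter
built from three modules:

* a **multi-scale inception module**: parallel 3×3, 5×5 and 7×7 stride-2
  convolutions, one per branch;
* a **multi-branch sampling module**: three skip-free encoder–decoder
  branches with total down/up-sampling 4×, 8× and 16×, each ending in its
  own 2-channel score map — small factors resolve small granules, large
  factors carry the context that rejects dark non-granular structures;
* a **multi-scale ensemble module**: the score maps are sliced per class,
  concatenated, fused by a learned 1×1 convolution, and passed through a
  softmax.

Training minimises pixel-wise cross-entropy with inverse-frequency class
weights (granules cover a small image fraction) using Adam.  The network is
implemented in pure numpy with hand-written backward passes, so it runs —
and trains, at desk scale — anywhere numpy does.  Instance splitting is a
marker-based watershed on the smoothed Euclidean distance transform, with
seeds at least one minimum granule radius apart; the round coefficient is
the isoperimetric ratio 4πA/P² (1 for a circle) with a Crofton perimeter
estimate, and membrane distances are measured edge-to-membrane from the
sub-pixel granule contour.  See `docs/methods.md` for every default and the
reasoning behind it.

## Worked example

Generate a synthetic micrograph at the high (disease-like) granule density,
split it into instances, and measure the population:

```python
import numpy as np
from granuleseg import (SceneSpec, generate_scene, watershed_instances,
                        filter_instances, measure_scene)
from granuleseg.morphometry import granule_density
from granuleseg.io_config import RunConfig

spec = SceneSpec(target_density_per_um2=2.3, seed=7)
truth = generate_scene(spec)
cfg = RunConfig(pixel_size_nm=spec.pixel_size_nm)

imap = watershed_instances(truth.granule_instances > 0,
                           cfg.min_seed_separation_px, cfg.smoothing_sigma_px)
imap = filter_instances(imap, cfg.min_area_px, cfg.max_area_px)
records = measure_scene(imap, truth.image, core_map=truth.core_instances,
                        membrane_polyline=truth.membrane_polyline)

print(f"granules generated: {truth.n_granules}, recovered: {len(records)}")
dens = granule_density([len(records)], [truth.cytoplasm_area_um2()])
print(f"density: {dens.mean:.2f} granules/um^2")
radii = [r.equiv_radius_nm for r in records]
print(f"equivalent radius: {np.mean(radii):.0f} +- {np.std(radii):.0f} nm")
print(f"round coefficient: {np.mean([r.round_coefficient for r in records]):.3f}")
docked = [r for r in records if r.membrane_distance_nm is not None
          and r.membrane_distance_nm < 40]
print(f"granules within 40 nm of the membrane: {len(docked)}")
```

Output:

```
granules generated: 18, recovered: 18
density: 2.93 granules/um^2
equivalent radius: 117 +- 31 nm
round coefficient: 0.999
granules within 40 nm of the membrane: 4
```

All 18 generated granules are recovered as separate instances (this single
scene happens to realise a density above its Poisson mean of 2.3/μm²; over
200 seeds the estimator recovers the mean within sampling error).  The round
coefficient near 1 says the granule outlines are circular; the four
granules within 40 nm of the membrane are the "docked" subpopulation.

The same stages are available from the shell:

```sh
granuleseg simulate --out scenes/ --n 20 --seed 7
granuleseg preprocess scenes/image_000.tif eq.tif
granuleseg train --data scenes/ --out model.npz --seed 0
granuleseg predict --model model.npz eq.tif --out mask.tif
granuleseg instances mask.tif --out inst.tif
granuleseg quantify inst.tif scenes/image_000.tif \
    --membrane scenes/membrane_000.json --out granules.csv
granuleseg evaluate --pred inst.tif --truth scenes/instances_000.tif \
    --iou 0.5 --out metrics.json
```

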
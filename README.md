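# ophiocount

Segment-and-count quantification of brittle stars (Ophiuroidea) in 2D
seabed mosaics.

Benthic video surveys are stitched into large 2D mosaic maps in which
hundreds of brittle stars must be counted. `ophiocount` implements the
full automated workflow for this task:

1. **Semantic segmentation** — a pyramid-pooling convolutional network
   predicts a per-pixel organism probability. Mosaics are
   block-processed with a sliding window (288 × 288 patches, stride
   144); overlapping patch predictions merge by mean, and the map is
   thresholded at 0.5.
2. **Instance counting** — the binary mask is cleaned by morphological
   opening (elliptical kernel) and a minimal-area filter, the Euclidean
   distance transform (EDT) is computed, its local maxima (minimum
   mutual distance 55 px, found per 8-connected component) seed a
   watershed on the negated EDT, and the number of watershed labels is
   the organism count.
3. **Evaluation** — pixel-level IOU = TP/(TP+FN+FP), a detected/ground-
   truth count ratio truncated to three decimals, and instance-level
   strict vs *forgiving* error accounting (forgiving mode excludes
   false positives that sit on a real organism and false negatives
   whose central disc is not visibly present).

Annotations come in two marker variants — the **full** star-like shape
with arms, or only the central body **disc** — with paired counting
parameters (kernel (2, 2) and min area 40 px for discs; (4, 4) and
120 px for full shapes).

Because the real survey mosaics cannot ship with the code, the package
includes a first-class synthetic scene generator: elliptical body discs
with five tapering curved arms on textured noisy background, optional
stitching-style artifacts (clipped, duplicated, or hidden-disc
organisms), and exact ground truth in both annotation variants. Every
stage of the pipeline is developed and tested against these scenes.

The segmentation network is implemented in pure NumPy (a compact
strided-convolution encoder at output stride 8, pyramid pooling over
bins {1, 2, 3, 6}, 1 × 1 fusion with dropout, bilinear upsampling and a
sigmoid head) with hand-written backpropagation and an Adam optimizer,
trained with an additive combination of soft-Jaccard and binary focal
losses. The `desk` encoder profile trains in a few minutes on one CPU
core.

## Worked example

```python
from ophiocount import (
    CountingConfig, ExperimentConfig, SceneConfig, count_pipeline,
    generate_scene, run_experiment,
)

# counting ground truth: a known scene counts back exactly
scene = generate_scene(SceneConfig(width=640, height=640, n_stars=20), seed=7)
labels, report = count_pipeline(scene.mask_disc, CountingConfig.for_variant("disc"))
print(report.blobs_detected)   # 20

# the full experiment: simulate, train, predict, count, evaluate
result = run_experiment(ExperimentConfig(seed=1), "out/")
print(round(result.iou, 3), result.blobs_detected,
      result.ground_truth_count, result.count_ratio)
# 0.769 97 97 1.0
```

The last line reads: on three held-out synthetic scenes the trained
desk-scale model reaches a pixel IOU of 0.769 against the disc ground
truth, and the counting workflow detects 97 blobs for 97 true
organisms — a count ratio of 1.0.

The same pipeline is available from the shell:

```sh
ophiocount simulate --out scenes/ --n-scenes 5 --seed 1
ophiocount train --data scenes/ --variant disc --out model/ --epochs 30
ophiocount predict --model model/ --image scenes/scene_0.png --out prob.tif
ophiocount count --mask prob.tif --variant disc --out report.json
ophiocount run --out experiment/ --seed 1
```

## Annotation JSON schema

```json
{
  "mosaic_id": "B5_0032_30s",
  "variant": "disc",
  "annotator": "expert-A",
  "polygons": [
    {"label": "brittle_star", "vertices": [[x, y], [x, y], ...]}
  ]
}
```

Coordinates are 0-based pixel centres, x rightward, y downward;
polygons are implicitly closed and need at least three vertices.

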
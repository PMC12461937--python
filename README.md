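# fimflow

Image-processing pipeline for **flow-imaging microscopy** of freshwater
phytoplankton.  Low-cost flow-imaging instruments photograph a water
sample as it passes a microfluidic channel; turning those widefield
frames into reliable particle counts and class abundances requires more
than a classifier: out-of-focus particles must be filtered, particles
stuck in the flow cell must not be counted once per frame, and objects
of types absent from the training set must be rejected rather than
silently assigned a label.  `fimflow` implements that whole chain, plus
a synthetic scene generator with exact ground truth so every stage is
testable without instrument data.

Stages (each a module, each a CLI subcommand):

| stage | module | method |
|---|---|---|
| scene simulation | `fimflow.synthgen` | parametric sprites on 468×352 px frames (725×545 µm at 1.55 µm/px), seeded targets + jittered stagnant background particles |
| object detection | `fimflow.segmenter` | background-deviation threshold → closing → 8-connected components; five-category scoring (TP/FP/FN/merge/split) |
| features | `fimflow.features` | 47 morphometric/intensity/edge-noise features per ROI; Pearson pruning; impurity-based ranking |
| focus filter | `fimflow.focus` | random forest, stratified 70:30 split, retrained on the top-12 features |
| background-particle detection | `fimflow.bpd` | DBSCAN on x–y positions over 3-frame windows → feature sub-clustering → 2-of-3 flagging |
| classification | `fimflow.classify` | micro-CNN (CONV-MP + 4×CONV-MP-DO + 2 dense, softmax), 8-fold dihedral augmentation, 70:15:15 split |
| rejection | `fimflow.openset` | SoftMax thresholding, Monte-Carlo dropout (50 passes), class-anchor clustering, KOC training; precision/recall/rejection-rate sweeps |

The core of the package is the **background-particle detector (BPD)**:
pairwise distances of all particles in three consecutive frames are
clustered with DBSCAN (user-set distance threshold); each position
cluster is sub-clustered by feature similarity so a moving particle
passing near a stagnant one is not swept up; a particle is flagged as
background only when its sub-cluster recurs in at least two of the
three frames.  With the calibrated threshold (22 px) the detector keeps
≥95 % detection for stagnant particles moving up to 20 px per frame and
exceeds 99 % per-particle accuracy on the seeded synthetic protocol.

## Worked example

Simulate a medium-density scene (15 flowing targets + 5 stagnant
background particles per frame, 30 frames), then segment, filter and
de-duplicate it:

```python
from fimflow import pipeline

report = pipeline.run_pipeline(
    {"seed": 11,
     "simulate": {"n_frames": 30, "n_targets_per_frame": 15, "n_background": 5}},
    "runs/demo",
)
print(report["counts"])
```

prints

```
{
  "frames": 30,
  "truth_particles": 600,
  "particles_segmented": 590,
  "particles_after_focus": 590,
  "focus_model_accuracy": 1.0,
  "particles_flagged_background": 149,
  "particles_after_bpd": 441,
  "estimated_concentration_per_ml": 185710.06
}
```

Reading: 600 rendered particles (450 unique targets + 5 background
particles re-imaged 30 times each); 590 detected (a few touching
targets merged); the focus filter removes nothing because all sprites
are rendered sharp; the BPD flags 149 of the ~150 background
observations, so counting the survivors gives 14.7 particles/frame —
about 1.9 × 10⁵ particles/mL through the 725 × 545 µm × 200 µm imaged
volume, instead of the ~30 % overcount a naive per-frame count would
give.

The same run from the shell:

```bash
fimflow run --config scene.yaml --out runs/demo
fimflow simulate --out runs/sim --seed 3          # individual stages
fimflow segment --in runs/sim/frames --out runs/seg
```

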
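# neurolapse

Automated morphometric analysis of long-term live-cell imaging of cultured
human motor neurons — as a tested, reusable Python pipeline with a built-in
synthetic data generator that supplies exact ground truth.

## The problem

Motor neurons (MNs) derived from human stem cells degenerate and die when
trophic-factor (TF) support — BDNF, GDNF, CNTF — is withdrawn, and can be
rescued when TFs are added back. Counting surviving cell bodies is a blunt
readout: morphology responds much earlier. In time-lapse fluorescence
imaging (one frame every 6 h for two weeks) each neuron can be segmented,
measured, and followed as an individual, which turns survival biology into
per-cell trajectories of morphometric features.

The central feature is the **node**: a location on the cell body from which
a neurite projects. Operationally, a node is a connected component of the
overlap between a narrow band around the soma boundary and the neurite
mask. Cells are classified by their (smoothed) node count *n*:

* **class A** — *n* ≥ 3, the most developed cells,
* **class B** — *n* ∈ {1, 2},
* **class C** — *n* = 0; these die quickly and cannot be tracked.

From classified trajectories the pipeline computes:

* **class A hours** — the time a cell that starts an analysis window in
  class A remains in class A before first switching to B or C (or
  disappearing);
* **fate-transition tables** — per-condition counts of A→{A,B,C} and
  B→{A,B,C} between the window start (day 6) and end (day 14), with the
  conservation identities `A→A + A→B + A→C = tracked A` (likewise for B)
  enforced on every table;
* **reverse tracking** — rescued class B cells (those that regain class A
  after TF addback) versus unrescued ones, compared on node count, cell
  body size, compactness and velocity at the addback time point.

Tracking follows the original assay's contract: cell bodies are linked
frame to frame by a score combining position, morphology and overlap
(`0.5·max(0, 1 − d/200 px) + 0.25·min(A₁,A₂)/max(A₁,A₂) + 0.25·IoU`),
solved as an optimal one-to-one assignment; minimum object size 50 px,
merge threshold 0.70 (fused objects are partitioned back into both
identities by nearest-seed pixels), splits ignored, trajectories shorter
than 5 frames discarded.

Because no imaging data ships with the pipeline, a first-class simulator
(`neurolapse.synthetic_data`) generates fluorescence-like movies of
Islet1::GFP-style neurons under four regimes — continuous support (TF+),
withdrawal at day 1 (TF−), withdrawal with addback at day 6/7/8, and a
soma-protective small molecule that keeps cells alive without restoring
neurite growth — together with the true per-cell state at every frame, so
every downstream stage is testable against exact ground truth.

## Worked example

Simulate an addback-at-day-6 culture, track it on ground truth, and compute
the fate metrics for the day 6→14 analysis window:

```python
from neurolapse.synthetic_data import (
    ConditionSpec, ImagingSchedule, SimulationConfig, simulate_culture,
)
from neurolapse.tracking import trajectories_from_ground_truth
from neurolapse.fate_analysis import (
    AnalysisWindow, class_a_hours, fate_transition_table, reverse_track,
)

schedule = ImagingSchedule()            # every 6 h for 14 days -> 57 frames
condition = ConditionSpec("addback_day6", tf_withdraw_day=1.0, tf_addback_day=6.0)
config = SimulationConfig(n_cells=110, schedule=schedule, condition=condition, seed=1)

gt = simulate_culture(config)
trajectories = trajectories_from_ground_truth(gt)
window = AnalysisWindow.from_days(6.0, 14.0, schedule)

table = fate_transition_table(trajectories, window, schedule, condition.name)
print(f"tracked A: {table.tracked_a}, tracked B: {table.tracked_b}")
print(f"A->A {table.a_to_a}  A->B {table.a_to_b}  A->C {table.a_to_c}")
print(f"B->A {table.b_to_a}  B->B {table.b_to_b}  B->C {table.b_to_c}")

hours = [h for t in trajectories
         if (h := class_a_hours(t, window, schedule)) is not None]
print(f"mean class A hours: {sum(hours)/len(hours):.1f} (n={len(hours)})")

rescued, unrescued = reverse_track(
    trajectories, schedule.frame_of_day(6.0), window, schedule)
print(f"rescued n={rescued.n} nodes {rescued.mean_node_count:.2f}; "
      f"unrescued n={unrescued.n} nodes {unrescued.mean_node_count:.2f}")
```

Output:

```
tracked A: 44, tracked B: 24
A->A 43  A->B 0  A->C 1
B->A 12  B->B 0  B->C 12
mean class A hours: 190.1 (n=44)
rescued n=12 nodes 1.83; unrescued n=12 nodes 1.42
```

Of the 110 plated cells, 68 were still trackable and in class A or B at
day 6. With TFs restored, nearly every class A cell stayed class A (hence
the mean class A hours close to the full 192 h window) and half of the
class B cells regrew to class A; the rescued half had more nodes at the
addback time point than the unrescued half — the signature that reverse
tracking is designed to recover. Under TF− the same seed yields `B->A 0`
and far shorter class A hours.

The rendered route works the same way on images:

```python
from neurolapse.synthetic_data import simulate_timelapse
from neurolapse.morphometry import SegmentationParams, process_stack
from neurolapse.tracking import TrackingParams, build_trajectories

stack, gt = simulate_timelapse(config)          # (57, H, W) uint16
per_frame = process_stack(stack, SegmentationParams(), schedule.pixel_size_um)
trajectories = build_trajectories(per_frame, TrackingParams())
```

## Command line

```
neurolapse run      --config config.yaml --out results/      # end to end
neurolapse simulate --config config.yaml --seed 1 --out sim/
neurolapse segment  --in sim/stack.tif --out seg/
neurolapse track    --obs seg/observations.csv --out trk/
neurolapse analyze  --traj trk/trajectories.csv --window 6:14 \
                    --addback-day 6 --out fate/
```

All stages read/write plain CSV (documented schemas), multi-page 16-bit
TIFF, and JSON summaries carrying the resolved configuration and seed.

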
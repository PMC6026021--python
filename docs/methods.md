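# Methods

## The simulated assay

The synthetic generator is an agent-based model of cultured motor neurons
on a dark background, written to emulate the conditions of the live-imaging
survival assay it supports: one 3.08 × 3.08 mm field imaged every 6 h for
14 days (57 frames), about 110 GFP-positive neurons per field at a
low-clumping plating density, and four condition regimes — continuous
trophic support (TF+), withdrawal at day 1 (TF−), withdrawal with addback
at day 6/7/8, and withdrawal plus a soma-protective agent applied for the
whole deprivation period.

Each cell carries a true state: position, soma radius, node count, one
length and one attachment angle per neurite, an alive flag, and (after the
addback time point) a rescuable flag. The state advances by discrete
per-frame updates with step `dt = interval_hours / 24` days:

* **node gain** (supported cells only): Bernoulli with probability
  `node_gain_rate_per_day · dt`; a new neurite starts at 20 µm at an angle
  at least 40° from existing attachments, up to 8 nodes;
* **node loss** (unsupported cells): Bernoulli with probability
  `node_loss_rate_per_day · dt`; the shortest neurite is removed;
* **neurite length**: grows at `neurite_growth_um_per_day` when supported,
  retracts at `neurite_retract_um_per_day` (floored at 8 µm) when not;
* **soma radius**: drift `soma_growth_um_per_day` up or
  `soma_shrink_um_per_day` down plus N(0, `soma_radius_jitter_um`) noise,
  clipped to [4, 16] µm;
* **death**: per-day hazard `base + hazard_per_missing_node · max(0, 3 − n)`
  converted to a per-step probability `min(1, h·dt)`; a dead cell freezes
  its state, keeps its id, and is never rendered again;
* **motility**: an isotropic random walk with fixed step length
  `motility_um_per_step`, reflected at a margin inside the field.

Because loss events are i.i.d. Bernoulli and the count is floored at zero,
the node count of an unsupported cell after `m` steps is distributed as
`max(0, n₀ − Binomial(m, p))` — the closed form the test suite checks the
implementation against, with an independent Monte-Carlo cross-check of the
formula itself.

**Addback and rescue.** At the addback frame each living cell draws a
rescuable flag with logistic probability
`σ(1.2·(n − 1.5) + 0.8·(r − 7 µm))` evaluated on its state at that frame;
rescuable cells revert to fully supported dynamics, the rest continue
deprived. One node is therefore worth about 1.5 µm of soma radius in the
rescue odds, so both covariates carry signal that reverse tracking should
recover. **The soma-protective agent** sets the death hazard to its
supported (base) value, stops soma shrinkage, and multiplies node loss by
`drug_node_loss_factor` (0.25), but never enables node gain: class A cells
persist while class B cells cannot develop — the dissociation that
distinguishes it from TF addback.

### Default rates and what anchors them

| parameter | default | rationale |
|---|---|---|
| initial nodes | 1 + Poisson(1.8) | mixed A/B population at the window start |
| node_gain_rate_per_day | 0.30 | supported cells reach the 4+ node modal category by day 14 |
| node_loss_rate_per_day | 0.15 | deprived cultures keep ~40% class B among tracked cells at day 6 |
| hazard | 0.01 + 0.15/missing node /day | most cells still trackable at day 6; class-C cells die in ~1–2 days; heavy B→C loss by day 14 |
| soma growth / shrink | 0.4 / 0.5 µm/day | visible size trend over two weeks within the 4–16 µm clip |
| neurite growth / retract | 8 / 12 µm/day | arbors of 50–150 µm per neurite at maturity |
| motility_um_per_step | 6 µm / 6 h | well below the ~290 µm mean spacing, so tracking is well posed |

These anchors are the printed per-condition tracked-cell tables of the
assay (≈100 tracked of ~110 at the day-6 window start; class B ≈ 40–50% of
tracked cells under deprivation; B→C the dominant class B fate without
rescue) and its qualitative time courses. They were fixed once at design
time; the directional tests then run at these defaults.

## Rendering

Frames are 16-bit grayscale: flat background (default 100 counts) with
additive Gaussian noise (sd 8), somata as filled disks at 1000 counts,
neurites as 3-px-wide curvilinear strokes at 400 counts starting on the
soma boundary at the recorded attachment angle. Stroke curvature is a
mean-reverting random walk seeded from (cell id, neurite index), so a
growing neurite keeps its shape across frames. Strokes steer around other
cells' somata (growth-cone-like deflection); without this, a stroke
passing straight through a neighboring soma is overdrawn by the disk and
leaves entry/exit stubs that are indistinguishable from true attachments —
no segmentation could score them correctly. Neurite–neurite crossings are
not prevented and do occur at high density. Pixel size defaults to
1.25 µm (2464 px across the 3.08 mm field); the value is configurable
since the original optics are not fully specified at this level.

The renderer omits several features of real data on purpose: no
photobleaching or focus drift, no glial background, no tile-stitching
seams, no intensity heterogeneity within a cell. Passing tests therefore
demonstrate correctness of the measurement and tracking logic under a
clean optical model, not robustness to every real-world artifact.

## Segmentation and measurement

* **Cell body filter**: Gaussian smoothing (σ 1 px) → absolute threshold
  (700 counts, halfway between neurite and soma intensity) → hole filling →
  removal of objects under 50 px → marker-based watershed on the distance
  transform (peak separation 10 px) to split touching somata.
* **Neurite filter**: absolute threshold (250 counts) conjoined with
  dilated tubeness (Sato ridge) support, minus soma interiors, with ≤ 3 px
  speckle removed. The 50 px size floor applies to somata only.
* **Nodes**: connected components of (soma boundary band ∩ neurite mask),
  band width 3 px, minimum component 3 px. A component must touch the soma
  boundary itself (8-adjacency) — a stroke merely passing through the band
  is not an attachment. Components contacting two bands go to the nearer
  soma centroid, ties to the lower label.
* **Measures**: area (px² and µm²), compactness `4πA/P²` clipped to 1,
  mean intensity, node count, and neurite length as the skeleton length
  (diagonal steps √2) of neurite components attached to the cell's band;
  components attached to several somata split their length equally — the
  attribution rule for shared arbors is a package choice, since no
  standard exists.

## Tracking

Links are scored `0.5·distance + 0.25·area-similarity + 0.25·IoU` with the
distance term `max(0, 1 − d/200 px)`; the score is zero beyond the search
range. Masks give exact IoU; when absent an equal-area disk approximation
is used. Per frame pair, the optimal one-to-one assignment over
positive-score pairs is solved exactly (Hungarian algorithm) — a
deterministic, strictly better reading of "join the highest score" than
greedy matching, and the exhaustive-search oracle in the tests pins the
contract for frames with ≤ 6 cells. Fused objects (both incoming
identities scoring above the 0.70 merge threshold against the fusion) are
partitioned by nearest-seed pixel assignment, so transiently overlapping
cells keep their ids. Splits are ignored: the best-scoring fragment keeps
the id, the rest seed new candidates. An identity unmatched for exactly
one frame may be re-acquired at twice the search range, with the skipped
frame filled by linear interpolation — the movie cadence is slow enough
that one dropped detection should not sever an identity. Trajectories
shorter than 5 frames are discarded. The 0.90 split threshold is retained
in the configuration for fidelity to the original settings but is inert
under the ignore-splits policy.

## Fate metrics

Node series are smoothed with a centered moving average (default window 3
frames = 18 h, the smallest centered window; edges shrink). Classification
applies half-up rounding to the smoothed value: A ≥ 3, B ∈ {1, 2}, C = 0.
Smoothed-series classification is the default (raw mode available): a
single-frame segmentation glitch should not flip a cell's class. The
analysis window is day 6 → day 14 unless configured otherwise.

* **Class A hours** is time-to-first-exit from class A, measured from the
  window start for cells in class A at the window start; the clock stops at
  the first non-A frame, at disappearance, or at the window end.
* **Fate tables** take the start class at the window-start frame and the
  end class at the window-end frame; a trajectory that ends early (lost or
  dead) is assigned end class C, since class C and death are effectively
  coupled in this system. Conservation identities are validated on every
  table the pipeline produces.
* **Reverse tracking** selects class-B-at-addback cells, calls rescued
  those reaching class A at any frame in (addback, window end], and reports
  group means ± SEM of node count, cell body size, compactness and
  velocity at the addback frame.

A small CSV of published per-condition mean fate tables (five-replicate
means from the TF-addback and soma-protective studies) ships with the
package as a consistency fixture. Two rows of the addback table carry
transcription artifacts (a duplicated class-B outcome triplet) and fail
the conservation identities by far more than printed rounding; the
residual check flags them (tolerance 0.05, the printed precision) and they
are excluded from validation.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 200 rendered cells (two
2.9 mm fields at plating density) for node recovery; a 100-cell, 57-frame
movie for tracking fidelity; 110-cell ground-truth cohorts over 5 seeds
for the directional contrasts; 200-cell cohorts over 5 seeds for reverse
tracking. These sizes give stable statistics while keeping a full run in
minutes on one CPU. All randomness flows from explicit integer seeds
through `numpy` generators; identical configuration and seed reproduce
byte-identical images and tables. Ties in node ownership and linking are
broken toward the lower label. Degenerate inputs (empty frames, empty
movies, all-background images, single-frame trajectories) return empty
results rather than errors wherever a valid empty answer exists.

## Known limitations

Ground-truth identity is recovered from rendered movies essentially
perfectly at default density and motility; the regime where cells clump or
move of order their spacing per frame is outside the validated envelope.
The hazard model is linear in missing nodes, which cannot simultaneously
produce very gentle class-B attrition and near-instant class-C death; the
default slope is a compromise favoring the printed day-6 cohort sizes.
Neurite length attribution for arbors shared between cells is a
convention. The statistical comparisons of the original study (repeated
measures ANOVA, post-tests) are deliberately not reimplemented; the tidy
long-format export is the interface to standard statistical software.
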
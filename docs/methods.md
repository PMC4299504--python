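# Methods

## Model

`budmorph` models the ureteric-bud / collecting-duct tree as a rooted tree
on a 2-D plane. A node record stores its mother, the length of the segment
from the mother, the signed angle of that segment relative to the mother's
direction, and its birth time; the root stores an absolute heading.
Positions are a pure function of this intrinsic geometry (preorder
accumulation of headings and segment vectors from the origin), which makes
every simulator operation an exact update of lengths and angles and keeps
re-derived coordinates bit-reproducible. The alternative — storing absolute
coordinates as primary state — would have made growth and length-based
retraction require whole-subtree rewrites; the intrinsic choice is a
reconstruction of the original model, not a documented property of it.

A run starts from an unbranched bud of length ε (`daughter_initial_length`)
and advances in steps of `dt`, applying in order:

1. **Growth** while `t < growth_end_time`: every segment length is
   multiplied by `exp(g·Δt)`. "Constant rate per unit length" is read as a
   proportional (exponential) law — the interpretation under which uniform
   cell proliferation along a tubule produces uniform relative elongation —
   and each step applies the exact factor, so trajectories are independent
   of `dt`. Each step is further split at bifurcation events and era
   boundaries, so even a `dt` that is not commensurate with the event grid
   yields the closed form `ε·exp(g·(growth_end − t_birth))` for every
   segment.
2. **Bifurcation** whenever `t` crosses `k·bifurcation_interval` strictly
   inside the growth era: every tip simultaneously becomes a branch point
   with two daughters of length ε at relative angles ∓`divergence/2` (an
   event exactly at `growth_end_time` does not fire). With
   `angle_jitter_sigma > 0`, independent Gaussian jitter is added to each
   daughter angle, consumed in ascending tip-id order (left before right)
   from a single generator seeded by `seed`, so runs are reproducible.
3. **Retraction** (when enabled) between `retraction_start_time` and
   `run_end_time`. Eligible segments are those ending at a node that has
   both a parent and two children: the central "pelvis" (root) segment and
   all terminal branches are exempt. Whether retraction originally ran
   strictly after growth or could overlap it is left open by the source
   description; both are supported, and the default starts retraction when
   growth ends.

## The two retraction geometries

- `length_based`: each eligible stalk length is multiplied by
  `exp(−ρ·Δt)`; relative angles and topology are untouched, so the
  daughter subtrees ride inward rigidly. This is exactly solvable
  (`L₀·exp(−ρ·Δt)`, step-size independent) and is the default, because the
  detection ground truth is unambiguous in this mode: every eligible stalk
  shrinks strictly monotonically, everything else is constant.
- `tip_anchored`: each eligible node is pulled along its stalk toward its
  parent by the factor `exp(−ρ·Δt)` while the current positions of all
  other nodes — in particular its daughters' distal endpoints — stay
  fixed; daughter lengths and relative angles are then recomputed from the
  fixed endpoints. Nodes are processed deepest-first within a step, each
  against its parent's not-yet-moved position. This reproduces the observed
  cell-level behaviour: the stalk of a 'Y' shortens, its arms lengthen,
  their divergence angle narrows, and the arm endpoints do not move
  circumferentially. Because a node's parent may itself move within the
  same step, the map is a genuine discrete dynamical system: it is not
  step-size independent and interior stalk lengths need not decrease
  monotonically (a shallow stalk can transiently lengthen while the
  collapse below feeds it).

An important and deliberately documented asymmetry follows from the
geometry: **only the anchored-tip mode radialises the tree.** Pure
length decay keeps every terminal segment's heading fixed while pulling its
origin toward the trunk, so the spread of terminal directions — and hence
the radial-alignment score — does not improve (it measurably worsens,
~75° vs ~65° for the growth-only tree under the defaults). With anchored
tips the terminal endpoints stay at the periphery while the internal
skeleton collapses centripetally, turning terminal segments into long,
almost parallel base-to-periphery rays (~36°). The package therefore uses
`tip_anchored` when reproducing the spread-to-radial transformation and
`length_based` for detection benchmarks; the radial-alignment comparison is
asserted across jittered replicates in the acceptance suite.

## Default parameters (reference study conditions)

| parameter | default | why |
| --- | --- | --- |
| `growth_rate` g | 0.35 /time | generation-to-generation length ratio e^0.35 ≈ 1.42, giving the graded fractal look of a young tree while keeping the youngest (tip) segments within a factor ~1.5 of the all-frames mean internode length |
| `retraction_rate` ρ | 1.0 /time | eligible stalks shrink by e^−2.5 ≈ 0.08 over the retraction era — a strong but not fully degenerate collapse |
| `bifurcation_interval` | 1.0 | five rounds (32 tips) fit in the growth era |
| `divergence_angle` | 93° | the measured value in cultured kidneys; 90° preset for the classical literature value |
| `daughter_initial_length` ε | 0.05 | not stated by the source model; a small seed length (reconstruction) |
| `growth_end_time` | 5.5 | events at t = 1…5 → 5 rounds |
| `run_end_time` | 8.0 | a 2.5-unit pure retraction era |
| `dt` | 0.05 | 160 steps; results are dt-independent for growth and length-based retraction anyway |
| `frame_interval` | 0.25 | 22 growth-era frames and 11 retraction-era frames, comfortably above the ≥ 20 points wanted for rate fitting and the ≥ 3 wanted for detection |
| `thickness_base`, `thickness_slope` | 1.0, 0.25 | rendering law base + slope·descendants |

"Thickness increases with the number of daughters (i.e. with age)" is
ambiguous between direct daughters (always two) and all descendants; the
descendant count is used as the only reading that actually grows with age.

## Morphometrics

Measurements act on *observed* per-frame coordinates (the fixture's noisy,
drifted ones when present; derived positions otherwise), the in-silico
analogue of measuring printed movie frames with a ruler. Internode length
is the Euclidean distance between a segment's endpoints per frame —
translation-invariant, so global drift cancels in lengths but not in
absolute positions; `register_frames` removes drift exactly by anchoring a
named node at the origin. Pelvis-to-periphery distance is exposed both as
the straight node-to-tip chord (`radial_growth_series`) and as the path
length along the branches (`path_length_series`), since both conventions
are in use.

`detect_retraction` smooths a length series with a centred moving mean of
width `smoothing_window` (3 frames by default), evaluated only where the
full window fits — partial edge windows would have a different effective
width and more variance — and calls a branch retracting when the smoothed
series falls more than `min_relative_drop` (5 % by default) below its
running maximum. The drop-from-running-max criterion, rather than net
first-to-last change, catches nodes whose rate varies or that pause and
resume, as real nodes do. The 5 % threshold is a reconstruction of a
visual judgement and is exposed as a parameter. `fraction_retracting`
applies the detector to every segment ending in a visible branch point
within an interval (segments are assessed over the frames in which they
exist; ones visible for fewer than `max(3, window)` frames are not
assessable and are excluded from the count).

`radial_alignment` scores a whole tree as the mean unsigned angle between
each terminal segment and the outward radial direction from the root base
to the segment's midpoint (0° = perfectly radial). The midpoint-based
reference is one of several defensible choices and is fixed for
reproducibility.

Exponential rates are recovered by least squares on log(length) vs time;
on noiseless series this is exact to numerical precision, and with 2 %
multiplicative length noise and ≥ 20 frames it recovers rates to a few
percent.

## Synthetic fixtures and what they do / do not show

`make_fixture` wraps a simulator run and perturbs every node coordinate in
every frame with independent isotropic Gaussian noise (scale σ), plus an
optional cumulative linear drift, writing SWC frames, a ground-truth label
table and a manifest; equal seeds give byte-identical output. The
reference fixture sets σ to 2 % of the mean internode length (mean over
all segments and frames of the clean run). Labels mark exactly the
eligible branch points as retracting, with onset at the later of the era
start and the node's own branching.

Noise is temporally uncorrelated and spatially isotropic, and drift is
linear — the simplest nuisance models. Real movies have correlated focus
drift, segmentation errors that delete or merge branches, trees that are
neither strictly bifurcating nor synchronised, and retraction that starts
per node rather than globally. Passing tests therefore demonstrate the
pipeline's correctness and its noise behaviour under these idealised
conditions, not performance on raw micrograph-derived skeletons.

Detection accuracy under the reference conditions is intentionally a
near-threshold problem: 2 %-of-mean coordinate noise puts ≈ 3 % noise on
tip-segment lengths against the 5 % drop criterion over an 11-frame era,
so the false-positive rate on tips is small but not negligible and the
per-replicate balanced accuracy fluctuates by a few points. The acceptance
suite therefore pools confusion counts over 10 fixture replicates
(~0.93 pooled balanced accuracy; clean data is error-free).

## Numerical choices and degenerate inputs

- Angles are degrees at every interface, radians only inside; relative
  angles are wrapped to (−180°, 180°].
- Zero-length segments keep their previous direction when geometry is
  rebuilt from positions (the direction of a null vector is undefined).
- Collinear daughters yield the degenerate divergence values 0° or 180°
  rather than an error.
- SWC floats are written with 9 decimals so identical trees give
  byte-identical files; SVG output is deterministic the same way.
- `frame_interval` must be an integer multiple of `dt`; bifurcation events
  are matched with a 1e−9 tolerance.
- Trees are validated for a single root, no cycles, at most two children
  and kind/structure consistency; unary chain nodes are tolerated (external
  skeletons may have them; the simulator never creates them).

## Known limitations

- 2-D only; no anastomoses, trifurcations or lateral branching; bifurcation
  is synchronous across tips.
- No pelvic enlargement or calyx expansion — retracted branches converge on
  a normal-calibre trunk.
- The anchored-tip mode is dt-dependent (documented above); its divergence
  narrowing and daughter elongation are guaranteed per step at a node whose
  daughters are not themselves retracting, and asserted in the tests on the
  canonical single-node geometry.
- Thickness/radius affects rendering only; it plays no mechanical role.
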
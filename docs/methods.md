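# Methods

## Problem and pipeline

Mammogram preprocessing for computer-aided detection starts by isolating
the breast tissue: everything outside the breast (patient markers, labels,
scanner artifacts — the *background partition*) and the pectoral muscle
(dense tissue whose intensity confounds mass detection) must be removed.
The pipeline is two stages applied in order to a single-channel image:
background-partition removal, then pectoral-muscle removal. All processing
assumes the right-sided layout (breast touching column 0, row 0 at the
top); a left-sided view is mirrored in and the result mirrored back, so a
single code path is authoritative for both views.

Pixels are carried in an unsigned 32-bit container regardless of the
source depth (8- or 16-bit PGM/PNG); stored samples are never rescaled.
The two scalar parameters are therefore on the image's own intensity
scale:

| parameter | meaning | default | rationale |
|---|---|---|---|
| `black` (B) | non-black iff value ≥ B | 1 | any nonzero pixel counts as tissue; phantoms keep background exactly 0 |
| `threshold` (T) | pectoral intensity floor | 70% of image max | a starting point only; T is data-dependent and must be user-set for real images |
| `pectoral_fraction` (f) | top-row band where ≥ T alone removes | 1/10 | boundary row count R = max(1, ⌊rows·f⌋); the minimum of 1 keeps the above-pixel rule well defined |
| `connectivity` | component adjacency | 4 | matches the streaming keep-rule, which uses only same-row runs and same-column adjacency; 8 available |

No numeric default of B or T is claimed to be correct for clinical data.

## The two formulations

**Reference (whole image).** Background: connected components of the
non-black mask via `scipy.ndimage.label`, relabelled to first-encounter
raster order; the largest is kept, ties broken toward the component whose
first pixel comes earliest in raster order (any deterministic rule would
do; this one is scan-order natural). Pectoral: an explicit per-pixel
top-down recurrence — zero (r,c) iff value ≥ T and (r < R or the processed
output at (r−1,c) is < B).

**Streaming (one pass, one row of state).** Both kernels scan top-down,
left-to-right, seeing each pixel exactly once. Two pieces of state exist:
the current row's leftmost maximal non-black run (*first run*), computable
online left-to-right, and a *line buffer* holding the previous **output**
row. Background: row 0 keeps only its first run; later rows zero a pixel
iff it is outside its row's first run *and* its above output pixel is
black. Pectoral: rows < R zero any pixel ≥ T; later rows additionally
require a black above output pixel.

The line buffer deliberately taps the kernel *output*, not the raw input.
With raw input, removal would not propagate down through detached
artifacts or through the wedge below row R; with output values the
streaming background kernel reproduces the largest-component rule on
structured images and the pectoral kernel is *identical* to the reference
recurrence on every image (property-tested on arbitrary random images).
Whether the original hardware tapped input or output is not documentable
from the design alone; the output tap is the only choice under which the
two formulations coincide.

**Conditions for background equivalence.** The one-pass keep-rule equals
"largest connected component" only on images where (i) the breast/pectoral
union is one 4-connected region touching column 0 in every row it
occupies, (ii) each row's leftmost non-black run belongs to that union,
and (iii) every union pixel outside its row's first run has a union pixel
directly above it. These are stated explicitly and enforced by
`validate_phantom_structure`, turning an implicit assumption into a
testable contract. A known failure mode outside the contract: an artifact
in row 0 left of the breast run would be adopted as the anchor and the
breast removed instead.

## Dataflow-graph form

The streaming kernels are additionally represented as explicit graphs of
typed nodes (stream/scalar ports, constants, counters, 32-bit comparators
with 1-bit outputs, 1-bit AND gates, unsigned 32-bit division, 2-to-1
muxes, a first-run detector and a line buffer) and evaluated one tick per
pixel: nodes fire in topological order of the combinational subgraph;
counters, line buffers and the run detector commit state after the tick.
The decision muxes carry the ids they have in the hardware design
(background: 22 for the first-row rule, 37 for the propagation rule;
pectoral: 19 and 35). A column counter wrapping at `cols` drives the row
counter (0..rows−1, step 1). "First run" and "above pixel" are realised as
dedicated stateful nodes rather than precomputed input streams.

Numerical choices: the pectoral boundary is computed on-graph as an
unsigned integer division; the max(1, ·) clamp is *not* wired, because
with the line buffer initialised to 0 (< B, since B ≥ 1) a boundary of 0
and of 1 are functionally identical on the first row — the equivalence
tests cover images with fewer than ten rows. Tick granularity is one
pixel; no clock latency or pipelining is modelled — functional
bit-exactness against the direct kernels is the contract, not cycle
accuracy. Graphs serialise to a plain node-list/edge-list text format for
inspection.

## Phantom generator

The generator emulates the geometry the contract requires, at the scale
the equivalence checks use (256×256 by default; one 4800×6400 phantom
exercises the full studied resolution): a breast drawn as a half-ellipse
attached to column 0 and occupying every row (width ≥ 1), a pectoral wedge
as a top-left right triangle with monotonically shrinking width (hence
column-anchored), and small disc artifacts strictly right of the breast
with at least one all-black column of separation. Intensities are banded —
breast in [B, T), pectoral in [T, ∞), defaults [30, 169] / [170, 255] on
an 8-bit-like scale — so the ground-truth ROI after segmentation is
exactly the breast mask. Noise (±10 by default) is added only inside masks
and clipped to each band, keeping the background exactly 0.

What the phantoms do *not* emulate: radiographic texture, the smooth
breast-edge intensity falloff, noise in the background, lesions, or
breast shapes that violate column anchoring. Passing tests therefore show
that the three implementations agree and that the pipeline is exact under
the stated structural assumptions — not that B and T chosen here segment
clinical mammograms well.

## Performance model

T_processing = cycles/frequency with one cycle per pixel per kernel pass
(the kernels consume one pixel per tick); T_PCIe = max(BytesIn/BandwidthIn,
BytesOut/BandwidthOut) with 4 bytes per pixel each way (32-bit streams),
overridable. Total time is max of the two terms, i.e. transfer and compute
overlap fully — consistent with treating the bus as the binding constraint
rather than an additive cost. k ≤ 8 parallel kernels (the engine's
eight-stream limit) process ⌈n/k⌉ sequential waves. The saturation point
is the smallest k with T_processing ≤ T_PCIe; past it the total is
constant, the plateau seen in acceleration curves. PCIe bandwidth is a
required user input (the bus rate of any particular card is a hardware
fact, not derivable here); the acceptance script uses a nominal 2 GB/s per
direction. Measured hardware speedups are out of scope — the model
reproduces the *shape* (monotone, then flat) and the algebra (exact
frequency scaling), which is what the tests assert.

## Problem sizes used by tests and the acceptance script

Chosen as the package's own test design: all 512 binary 3×3 images
(exhaustive labelling oracle, both connectivities); 100 phantoms at
256×256 for stream-vs-reference equality; 200 random images ≤ 32×32 with
random B, T for graph-vs-kernel equality; 500 random images ≤ 24×24 for
the pectoral recurrence identity; 100 phantoms at 64×64 for idempotence;
one 4800×6400 phantom end to end; a grid over {75, 200} MHz ×
{1024×1024, 4800×6400} × three bandwidths for the model.

## Known limitations

- B and T are inputs, not estimated (no Otsu-style auto-thresholding).
- The streaming background kernel is only guaranteed on images meeting the
  structural contract; arbitrary images may keep detached bright regions
  connected to nothing above (e.g. an artifact touching row 0's first run).
- Batch processing is sequential-equivalent; no concurrency is modelled.
- The graph evaluator is functional, not cycle-accurate, and the exact
  arithmetic-node wiring beyond the named muxes/counter is a
  reconstruction constrained by behaviour, not a netlist copy.
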
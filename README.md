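# mammroi

Region-of-interest (ROI) extraction for breast mammograms: remove the
background partition (labels, markers, scanner artifacts detached from the
breast) and the pectoral muscle (the dense, bright wedge in the top corner
of mediolateral views), leaving only breast tissue for downstream mass and
microcalcification detection.

The same segmentation is implemented three interchangeable ways:

1. **reference** — whole-image computations: keep the largest connected
   component of non-black pixels, then apply a top-down thresholding
   recurrence for the pectoral wedge;
2. **stream** — single-pass raster-scan kernels that see each pixel once and
   keep only one row of state (a line buffer of the previous *output* row),
   the form in which the algorithm maps onto a streaming FPGA dataflow
   engine;
3. **graph** — the streaming kernels expressed as explicit dataflow graphs
   of typed operator nodes (multiplexers, comparators, counters, a line
   buffer) and evaluated one tick per pixel.

On images satisfying the structural assumptions of a mammogram (breast
anchored at the chest-wall edge, column-anchored growth, detached
artifacts) all three are bit-identical; a synthetic phantom generator
produces such images with ground-truth masks, so no clinical data is needed
to test any of it. An analytic performance model captures when a bank of
k ≤ 8 parallel streaming kernels stops helping because the PCIe bus
saturates.

## The model

Let B ≥ 1 be the *black level* (a pixel is non-black iff its value ≥ B) and
T the *pectoral threshold*, both absolute values on the image's own scale.

**Background removal.** Label the 4-connected (optionally 8-connected)
components of `{(r,c) : I(r,c) ≥ B}`; keep the largest, zero the rest.
The streaming form keeps, in each row, the leftmost maximal non-black run
(the breast's anchor) and any pixel whose *above* output pixel is
non-black; on anchored, column-connected images this equals the
largest-component rule.

**Pectoral removal.** With R = max(1, ⌊rows · f⌋) (f = 1/10 by default),

    O(r,c) = 0      if I(r,c) ≥ T and ( r < R  or  O(r−1,c) < B )
    O(r,c) = I(r,c) otherwise,

a top-down recurrence: the wedge is thresholded unconditionally in the top
rows and the removal propagates down each column through the processed
output. The streaming and reference forms of this stage agree on *every*
image, not just phantoms.

**Performance model.** With one cycle per pixel per kernel pass,

    T_processing = cycles / frequency
    T_PCIe       = max(BytesIn / BandwidthIn, BytesOut / BandwidthOut)
    T_total      = max(T_processing, T_PCIe)        (full overlap)

k parallel kernels split n images into ⌈n/k⌉ waves, shrinking
T_processing only; the *saturation point* is the smallest k at which
T_processing ≤ T_PCIe — beyond it extra kernels change nothing.

## Worked example

```python
import numpy as np
from mammroi import (PhantomSpec, generate_phantom, default_seg_params,
                     ROISegmenter, segment_reference, PerfScenario,
                     report_table, saturation_point)

spec = PhantomSpec(rows=256, cols=256, seed=7)
ph = generate_phantom(spec)
params = default_seg_params(spec)
print("B =", params.black, " T =", params.threshold)
print("non-black input pixels:", int((ph.image > 0).sum()))

seg = ROISegmenter(threshold=params.threshold, engine="stream")
roi = seg.fit_transform(ph.image)
print("ROI pixels kept:       ", int((roi > 0).sum()))
print("ROI == breast mask:    ", bool(np.array_equal(roi > 0, ph.breast_mask)))
print("stream == reference:   ", bool(np.array_equal(roi, segment_reference(ph.image, params))))
```

prints

```
B = 1  T = 170
non-black input pixels: 42961
ROI pixels kept:        41874
ROI == breast mask:     True
stream == reference:    True
```

— of the 42 961 non-black pixels, the 1 087 belonging to the pectoral wedge
and the detached artifacts are removed and the ROI equals the ground-truth
breast mask exactly, with the one-pass kernel reproducing the whole-image
reference bit for bit. The estimators follow scikit-learn conventions
(`fit`/`transform`, `get_params`, pipeline-compatible); plain functions
(`segment_stream`, `segment_reference`, ...) expose the same operations.

The performance model for eight 1024×1024 images at 200 MHz over a
2 GB/s-per-direction bus:

```python
scenario = PerfScenario.for_image(1024, 1024, frequency=200e6,
                                  bandwidth_in=2e9, bandwidth_out=2e9, n_images=8)
print(report_table(scenario)); print("saturation k:", saturation_point(scenario))
```

```
k	processing_s	pcie_s	total_s	speedup_vs_k1
1	0.04194304	0.016777216	0.04194304	1
2	0.02097152	0.016777216	0.02097152	2
3	0.01572864	0.016777216	0.016777216	2.5
4	0.01048576	0.016777216	0.016777216	2.5
...
saturation k: 3
```

— from three kernels on, the run is transfer-bound and the total time
plateaus at the PCIe term.

## Command line

```sh
mammroi phantom --rows 256 --cols 256 --seed 0 -o out/      # image + masks
mammroi segment out/phantom_image.pgm --threshold 170 --engine stream
mammroi batch img1.pgm ... img8.pgm --threshold 170         # ≤ 8 per batch
mammroi graph-sim --kernel background --dump --rows 8 --cols 8
mammroi perf --rows 1024 --cols 1024 --frequency 200e6 --bw-in 2e9 --bw-out 2e9
```

`segment --engine stream|reference|graph` produce byte-identical output
files on structure-valid images. A `key=value` config file (`--config`)
supplies any option; command line > config > defaults.

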
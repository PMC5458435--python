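"""Shared test utilities: independent oracles and random-input factories."""

import numpy as np

from mammroi import SegParams


def flood_fill_components(mask, connectivity=4):
    """Independent oracle: label connected True-pixels by flood fill in
    first-encounter raster order.  Returns (labels, sizes)."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    sizes = {}
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    next_label = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                next_label += 1
                stack = [(r, c)]
                labels[r, c] = next_label
                count = 0
                while stack:
                    rr, cc = stack.pop()
                    count += 1
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = next_label
                            stack.append((nr, nc))
                sizes[next_label] = count
    return labels, sizes


def random_image(rng, max_side=16, max_value=16):
    r = int(rng.integers(1, max_side + 1))
    c = int(rng.integers(1, max_side + 1))
    return rng.integers(0, max_value, size=(r, c)).astype(np.uint32)


def random_params(rng, max_value=16):
    return SegParams(
        black=int(rng.integers(1, max(2, max_value // 2))),
        threshold=int(rng.integers(1, max_value)),
    )
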
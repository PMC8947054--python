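"""Independent brute-force oracles the pipeline is checked against.

Deliberately naive: per-pixel loops and explicit flood fill, no shared code
with the implementation under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def median_filter_oracle(img: np.ndarray, radius: int) -> np.ndarray:
    """Per-pixel disc-neighborhood median with symmetric boundary padding."""
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    padded = np.pad(img, radius, mode="symmetric")
    out = np.empty_like(img)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            vals = [padded[r + radius + dr, c + radius + dc] for dr, dc in offsets]
            out[r, c] = np.median(vals)
    return out


def truth_table_areas(gfp: np.ndarray, rfp: np.ndarray, myh: np.ndarray) -> dict[str, int]:
    """Count pixels of each fusion class by enumerating the 8 boolean combos."""
    counts = {"MT_GFP": 0, "MT_RFP": 0, "MT_DUAL": 0, "UNCLASSIFIED": 0}
    for r in range(myh.shape[0]):
        for c in range(myh.shape[1]):
            if not myh[r, c]:
                continue
            g, f = bool(gfp[r, c]), bool(rfp[r, c])
            if g and f:
                counts["MT_DUAL"] += 1
            elif g:
                counts["MT_GFP"] += 1
            elif f:
                counts["MT_RFP"] += 1
            else:
                counts["UNCLASSIFIED"] += 1
    return counts


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[int]:
    """Connected-component areas via explicit BFS; sorted ascending."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    visited = np.zeros(mask.shape, dtype=bool)
    areas = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if not mask[r0, c0] or visited[r0, c0]:
                continue
            area = 0
            queue = deque([(r0, c0)])
            visited[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                area += 1
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < mask.shape[0]
                        and 0 <= cc < mask.shape[1]
                        and mask[rr, cc]
                        and not visited[rr, cc]
                    ):
                        visited[rr, cc] = True
                        queue.append((rr, cc))
            areas.append(area)
    return sorted(areas)
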
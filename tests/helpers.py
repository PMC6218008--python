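"""Independent brute-force oracles shared by several test modules."""

from collections import deque

import numpy as np

NEIGHBORS_4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
NEIGHBORS_8 = NEIGHBORS_4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]


def brute_force_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components by breadth-first flood fill (no scipy)."""
    mask = np.asarray(mask, dtype=bool)
    offsets = NEIGHBORS_4 if connectivity == 4 else NEIGHBORS_8
    seen = np.zeros_like(mask)
    components = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            queue = deque([(r, c)])
            seen[r, c] = True
            comp = set()
            while queue:
                rr, cc = queue.popleft()
                comp.add((rr, cc))
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not seen[nr, nc]:
                        seen[nr, nc] = True
                        queue.append((nr, nc))
            components.append(frozenset(comp))
    return components


def ellipse_pixels(center, semi_major, semi_minor, orientation_deg, shape) -> set:
    """Direct per-pixel evaluation of the ellipse inclusion inequality."""
    cx, cy = center
    theta = np.radians(orientation_deg)
    ux, uy = np.cos(theta), -np.sin(theta)
    pixels = set()
    for r in range(shape[0]):
        for c in range(shape[1]):
            dx, dy = c - cx, r - cy
            pm = dx * ux + dy * uy
            pn = -dx * uy + dy * ux
            if (pm / semi_major) ** 2 + (pn / semi_minor) ** 2 <= 1.0:
                pixels.add((r, c))
    return pixels
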
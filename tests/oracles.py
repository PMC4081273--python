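"""Independent brute-force oracles used to validate the library.

These deliberately use naive algorithms (BFS flood fill, exhaustive
suppression scans) that share no code with the implementations they check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(binary: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Label components by BFS flood fill, row-major first-encounter order."""
    binary = np.asarray(binary).astype(bool)
    h, w = binary.shape
    if connectivity == 1:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r in range(h):
        for c in range(w):
            if binary[r, c] and labels[r, c] == 0:
                current += 1
                queue = deque([(r, c)])
                labels[r, c] = current
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels, current


def exhaustive_peaks(image: np.ndarray, min_distance: int) -> np.ndarray:
    """Strict-window local maxima plus greedy Euclidean suppression,
    computed with explicit loops."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    candidates = []
    for r in range(h):
        for c in range(w):
            v = image[r, c]
            strict = True
            for dr in range(-min_distance, min_distance + 1):
                for dc in range(-min_distance, min_distance + 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < h and 0 <= nc < w and image[nr, nc] >= v:
                        strict = False
                        break
                if not strict:
                    break
            if strict:
                candidates.append((r, c, v))
    candidates.sort(key=lambda t: (-t[2], t[0], t[1]))
    accepted = []
    for r, c, _ in candidates:
        if all(np.hypot(r - ar, c - ac) >= min_distance for ar, ac in accepted):
            accepted.append((r, c))
    return np.asarray(accepted, dtype=np.intp).reshape(-1, 2)
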
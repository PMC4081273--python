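"""Connected-component labeling core (shared by measure and canny hysteresis).

Classic two-pass union-find over the ON pixels of a binary image, scanning
in row-major order.  Final labels are renumbered 1..n in order of first
encounter, which makes labelings deterministic and therefore directly
comparable across runs and implementations.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = {
    1: ((-1, 0), (0, -1)),  # 4-neighborhood: N, W already visited
    2: ((-1, -1), (-1, 0), (-1, 1), (0, -1)),  # 8-neighborhood adds diagonals
}


def label_components(binary: np.ndarray, connectivity: int = 2):
    """Label connected components of `binary`.

    Returns ``(labels, n_labels)`` where `labels` is an int32 grid with 0
    for background and components numbered 1..n_labels in row-major
    first-encounter order.
    """
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-n'hood) or 2 (8-n'hood)")
    binary = np.asarray(binary).astype(bool)
    h, w = binary.shape
    labels = np.zeros((h, w), dtype=np.int32)
    parent = [0]  # union-find; parent[i] == i marks a root

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    offsets = _OFFSETS[connectivity]
    rows, cols = np.nonzero(binary)
    for r, c in zip(rows.tolist(), cols.tolist()):
        roots = set()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and labels[rr, cc]:
                roots.add(find(labels[rr, cc]))
        if not roots:
            parent.append(len(parent))
            labels[r, c] = len(parent) - 1
        else:
            keep = min(roots)
            labels[r, c] = keep
            for other in roots:
                parent[other] = keep

    final = {}
    out = np.zeros((h, w), dtype=np.int32)
    for r, c in zip(rows.tolist(), cols.tolist()):
        root = find(labels[r, c])
        if root not in final:
            final[root] = len(final) + 1
        out[r, c] = final[root]
    return out, len(final)
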
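"""Shared punctum-extraction core: nearest-local-maximum basin assignment.

Supra-threshold pixels are assigned to local intensity maxima of a guide
surface by deterministic hill climbing (8-connectivity).  Plateau ties are
broken toward the lexicographically smallest (row, col) coordinate, so
labelling is fully reproducible.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def assign_to_local_maxima(
    surface: np.ndarray, mask: np.ndarray, min_area: int = 9
) -> np.ndarray:
    """Partition ``mask`` pixels into basins of attraction of local maxima.

    Each masked pixel climbs to its best 8-neighbour (highest ``surface``
    value; ties toward smallest (row, col)); pixels that are their own best
    candidate are basin roots.  Basins smaller than ``min_area`` pixels are
    discarded.  Returns an int label image, 0 = background, labels 1..K
    ordered by root coordinate.
    """
    surface = np.asarray(surface, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if surface.shape != mask.shape:
        raise ValueError("surface and mask shapes differ")
    h, w = surface.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if not mask.any():
        return labels

    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # Best candidate starts as the pixel itself.
    best_val = np.where(mask, surface, -np.inf)
    best_r = rows.copy()
    best_c = cols.copy()

    pad_val = np.full((h + 2, w + 2), -np.inf)
    pad_val[1:-1, 1:-1] = np.where(mask, surface, -np.inf)
    for dy, dx in _OFFSETS:
        nv = pad_val[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        nr = rows + dy
        nc = cols + dx
        better = (nv > best_val) | (
            (nv == best_val)
            & ((nr < best_r) | ((nr == best_r) & (nc < best_c)))
            & np.isfinite(nv)
        )
        best_val = np.where(better, nv, best_val)
        best_r = np.where(better, nr, best_r)
        best_c = np.where(better, nc, best_c)

    parent = np.arange(h * w, dtype=np.int64)
    flat_mask = mask.ravel()
    parent[flat_mask] = (best_r * w + best_c).ravel()[flat_mask]
    # Pointer jumping until every masked pixel points at its basin root.
    while True:
        grand = parent[parent]
        if np.array_equal(grand, parent):
            break
        parent = grand

    roots = np.unique(parent[flat_mask])
    # Deterministic labels: roots sorted by flat index == (row, col) order.
    root_to_label = {r: i + 1 for i, r in enumerate(np.sort(roots))}
    lab_flat = labels.ravel()
    lab_flat[flat_mask] = [root_to_label[p] for p in parent[flat_mask]]
    labels = lab_flat.reshape(h, w)

    # Area filter, then contiguous relabel 1..K.
    if min_area > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    kept = np.unique(labels)
    kept = kept[kept > 0]
    remap = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    remap[kept] = np.arange(1, kept.size + 1, dtype=np.int32)
    return remap[labels]
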
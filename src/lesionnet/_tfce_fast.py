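"""Union-find TFCE sweep, numba-compiled.

Computes the same discrete sum as the per-threshold labeling in
:mod:`lesionnet.map_stats` (thresholds h = dh..n_steps*dh, cluster extents
by the given neighbor offsets) in one pass over voxels sorted by height:
descending thresholds activate voxels incrementally and merge components,
so each threshold only costs the active-voxel accumulation.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _find(parent: np.ndarray, v: int) -> int:
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:  # path compression
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=True)
def _tfce_kernel(
    xf: np.ndarray,
    ni: int,
    nj: int,
    nk: int,
    offs: np.ndarray,
    E: float,
    H: float,
    dh: float,
    n_steps: int,
) -> np.ndarray:
    n = xf.size
    order = np.argsort(-xf)
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    active = np.zeros(n, dtype=np.uint8)
    out = np.zeros(n, dtype=np.float64)
    ptr = 0
    heps = 1e-9 * dh
    for step in range(n_steps, 0, -1):
        h = step * dh
        while ptr < n:
            v = order[ptr]
            if xf[v] < h - heps or xf[v] <= 0.0:
                break
            ptr += 1
            parent[v] = v
            size[v] = 1
            active[v] = 1
            i = v // (nj * nk)
            rem = v % (nj * nk)
            j = rem // nk
            k = rem % nk
            for o in range(offs.shape[0]):
                ii = i + offs[o, 0]
                jj = j + offs[o, 1]
                kk = k + offs[o, 2]
                if 0 <= ii < ni and 0 <= jj < nj and 0 <= kk < nk:
                    w = (ii * nj + jj) * nk + kk
                    if active[w] == 1:
                        ra = _find(parent, v)
                        rb = _find(parent, w)
                        if ra != rb:  # union by size
                            if size[ra] < size[rb]:
                                ra, rb = rb, ra
                            parent[rb] = ra
                            size[ra] += size[rb]
        hh = h**H * dh
        for idx in range(ptr):
            v = order[idx]
            r = _find(parent, v)
            out[v] += size[r] ** E * hh
    return out


def tfce_sweep(
    x: np.ndarray, offsets: np.ndarray, E: float, H: float, dh: float, n_steps: int
) -> np.ndarray:
    if n_steps <= 0:
        return np.zeros_like(x)
    ni, nj, nk = x.shape
    out = _tfce_kernel(x.ravel(), ni, nj, nk, offsets, E, H, dh, n_steps)
    return out.reshape(x.shape)
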
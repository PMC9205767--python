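"""Independent brute-force reference implementations used only by tests.

Each function here deliberately avoids the code paths (and where possible
the libraries) used by the package itself: textbook formulas, explicit
loops, exhaustive enumeration. Slow and simple on purpose.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_r(x, y) -> float:
    """Textbook Pearson correlation via explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def fisher_z_scalar(r: float) -> float:
    """atanh via the log identity, independent of numpy.arctanh."""
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def mann_whitney_u(x, y) -> float:
    """U for sample x by exhaustive pair counting with half-ties."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def ols_contrast_t(X: np.ndarray, c: np.ndarray, y: np.ndarray) -> float:
    """OLS t for contrast c via explicit normal equations."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = math.sqrt(sigma2 * float(c @ XtX_inv @ c))
    return float(c @ beta) / se


def _neighbors(ijk, shape, connectivity):
    """Neighbor offsets for 6/18/26 connectivity, explicit enumeration."""
    i, j, k = ijk
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                ni, nj, nk = i + di, j + dj, k + dk
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
                    out.append((ni, nj, nk))
    return out


def cluster_size_at(x: np.ndarray, voxel, h: float, connectivity: int = 26) -> int:
    """Size of the suprathreshold cluster containing ``voxel``, by BFS flood fill."""
    if x[voxel] < h:
        return 0
    seen = {voxel}
    frontier = [voxel]
    while frontier:
        cur = frontier.pop()
        for nb in _neighbors(cur, x.shape, connectivity):
            if nb not in seen and x[nb] >= h:
                seen.add(nb)
                frontier.append(nb)
    return len(seen)


def tfce_brute(x: np.ndarray, E: float, H: float, n_steps: int = 100,
               connectivity: int = 26) -> np.ndarray:
    """Per-voxel TFCE of a nonnegative map via per-voxel flood fills.

    For every voxel independently: sweep thresholds h = dh, 2dh, ... <= max,
    find the size of the cluster containing that voxel at each h, and sum
    size^E * h^H * dh. O(voxels^2 * steps) -- tiny maps only.
    """
    x = np.asarray(x, float)
    hmax = float(x.max(initial=0.0))
    out = np.zeros_like(x)
    if hmax <= 0:
        return out
    dh = hmax / n_steps
    for ijk in np.argwhere(x > 0):
        ijk = tuple(ijk)
        total = 0.0
        for k in range(1, n_steps + 1):
            h = k * dh
            size = cluster_size_at(x, ijk, h - 1e-9 * dh, connectivity)
            if size == 0:
                break
            total += size**E * h**H * dh
        out[ijk] = total
    return out


def mixed_anova_interaction_f(values_a, values_b, groups) -> float:
    """2x2 mixed ANOVA (ROI within, group between) interaction F, explicit SS.

    values_a / values_b: per-subject means in ROI A and B; groups: binary
    labels. Classic sums-of-squares decomposition.
    """
    values_a = np.asarray(values_a, float)
    values_b = np.asarray(values_b, float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    assert len(levels) == 2
    # cell means
    grand = np.mean(np.concatenate([values_a, values_b]))
    ss_inter = 0.0
    for lev in levels:
        for vals, roi_mean_all in ((values_a[groups == lev], values_a.mean()),
                                   (values_b[groups == lev], values_b.mean())):
            cell_mean = vals.mean()
            group_mean = np.mean(
                np.concatenate([values_a[groups == lev], values_b[groups == lev]])
            )
            ss_inter += len(vals) * (cell_mean - group_mean - roi_mean_all + grand) ** 2
    # error: within-subject (ROI x subject within group)
    d = values_a - values_b
    ss_err = 0.0
    for lev in levels:
        dd = d[groups == lev]
        ss_err += np.sum((dd - dd.mean()) ** 2) / 2.0  # per-ROI split of subject x ROI SS
    n = len(values_a)
    df_err = n - 2
    return (ss_inter / 1.0) / (ss_err / df_err)
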
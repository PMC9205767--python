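"""Therapeutic-target hub maps.

Which single voxels have a whole-brain connectivity profile that best
matches (or anti-matches) the remission network? Each in-mask voxel is used
as a single-voxel seed through the same lesion-network machinery, its
combined connectivity profile is spatially correlated with the reference
map (the voxel's own trivially-perfect self-correlation is excluded from
the support), and the resulting match map is thresholded at r > 0.75 and
r < -0.75 to nominate positive (lesion/inhibition) and negative
(excitatory-stimulation) targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lnm_core import Connectome, fisher_z, to_vector, to_volume
from .volume_io import BinaryMask, Volume

__all__ = ["HubMap", "hub_match_map", "extract_peaks", "overlap_report"]


@dataclass
class HubMap:
    """Per-voxel spatial correlation with the reference network."""

    match_r: Volume
    positive_threshold: float = 0.75
    negative_threshold: float = -0.75

    def thresholded(self, sign: str) -> BinaryMask:
        vals = np.nan_to_num(np.asarray(self.match_r.data), nan=0.0)
        if sign == "positive":
            sel = vals > self.positive_threshold
        elif sign == "negative":
            sel = vals < self.negative_threshold
        else:
            raise ValueError("sign must be 'positive' or 'negative'")
        return BinaryMask(
            sel.astype(np.uint8),
            self.match_r.affine,
            self.match_r.space,
            allow_empty=True,
        )


def _seed_profiles(
    connectome: Connectome, seed_cols: np.ndarray
) -> np.ndarray:
    """Mean Fisher-z profile of each single-voxel seed (S x V).

    Same combination rule as lesion network maps (mean of per-subject
    Fisher-z maps) so hub matching and lesion mapping share one definition.
    """
    V = connectome.n_voxels
    S = len(seed_cols)
    acc = np.zeros((S, V))
    for ts in connectome.subjects.values():
        x = ts - ts.mean(axis=0, keepdims=True)
        ss = np.einsum("tv,tv->v", x, x)
        seeds = x[:, seed_cols]  # T x S
        num = seeds.T @ x  # S x V
        denom = np.sqrt(np.outer(ss[seed_cols], ss))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        acc += np.asarray(fisher_z(np.clip(r, -1.0, 1.0)))
    return acc / connectome.n_subjects


def hub_match_map(
    connectome: Connectome,
    reference: Volume | np.ndarray,
    stride: int = 1,
    positive_threshold: float = 0.75,
    negative_threshold: float = -0.75,
    chunk: int = 256,
) -> HubMap:
    """Correlate every voxel's connectivity profile with a reference map.

    ``stride`` subsamples the seed voxels (pure subsampling on the mask's
    C-order voxel list, no interpolation; skipped voxels carry NaN). The
    correlation support excludes the seed voxel itself, via closed-form
    leave-one-out moment corrections so the whole map stays vectorised.
    """
    bm = connectome.brain_mask
    V = bm.n_voxels
    if stride < 1 or stride > V:
        raise ValueError("stride must be in [1, n_voxels]")
    ref = (
        to_vector(reference, bm)
        if isinstance(reference, Volume)
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (V,):
        raise ValueError("reference is not on the connectome grid")
    seed_cols = np.arange(0, V, stride)
    out = np.full(V, np.nan)
    # reference moments over the full support, corrected per seed below
    Sx = ref.sum()
    Sxx = float(ref @ ref)
    for start in range(0, len(seed_cols), chunk):
        cols = seed_cols[start : start + chunk]
        P = _seed_profiles(connectome, cols)  # S x V
        Sy = P.sum(axis=1)
        Syy = np.einsum("sv,sv->s", P, P)
        Sxy = P @ ref
        # leave out each seed's own (self) voxel from the support
        self_y = P[np.arange(len(cols)), cols]
        self_x = ref[cols]
        n = V - 1
        sy = Sy - self_y
        syy = Syy - self_y**2
        sx = Sx - self_x
        sxx = Sxx - self_x**2
        sxy = Sxy - self_x * self_y
        cov = sxy - sx * sy / n
        varx = sxx - sx**2 / n
        vary = syy - sy**2 / n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(np.maximum(varx * vary, 1e-300))
        out[cols] = np.clip(r, -1.0, 1.0)
    return HubMap(
        match_r=to_volume(out, bm),
        positive_threshold=positive_threshold,
        negative_threshold=negative_threshold,
    )


def extract_peaks(
    hub: HubMap, k: int = 10, min_distance_vox: float = 3.0
) -> pd.DataFrame:
    """Ranked local peaks of |match_r| above the hub thresholds.

    Suprathreshold voxels are visited in descending |r|; a voxel becomes a
    peak unless it lies within ``min_distance_vox`` of an already-accepted
    peak (greedy separation). Peaks are reported in world mm via the map's
    affine, with their signed r. Raises if nothing is suprathreshold.
    """
    vals = np.asarray(hub.match_r.data, dtype=float)
    finite = np.nan_to_num(vals, nan=0.0)
    supra = (finite > hub.positive_threshold) | (finite < hub.negative_threshold)
    if not supra.any():
        raise ValueError("no suprathreshold voxels to extract peaks from")
    idx = np.argwhere(supra)
    order = np.argsort(-np.abs(finite[supra]))
    idx = idx[order]
    peaks: list[np.ndarray] = []
    rows = []
    for ijk in idx:
        if len(peaks) >= k:
            break
        if peaks and np.min(np.linalg.norm(np.array(peaks) - ijk, axis=1)) < min_distance_vox:
            continue
        peaks.append(ijk)
        world = hub.match_r.voxel_to_world(ijk)[0]
        r = float(finite[tuple(ijk)])
        rows.append(
            {
                "x_mm": world[0],
                "y_mm": world[1],
                "z_mm": world[2],
                "r": r,
                "sign": "positive" if r > 0 else "negative",
            }
        )
    return pd.DataFrame(rows)


def overlap_report(hub: HubMap, rois: dict[str, BinaryMask]) -> pd.DataFrame:
    """Descriptive overlap of the thresholded hub map with named ROIs.

    For each ROI: voxel count of overlap with the suprathreshold set (both
    signs pooled) and the peak |r| value inside the ROI (NaN if none).
    """
    vals = np.nan_to_num(np.asarray(hub.match_r.data), nan=0.0)
    supra = (
        hub.thresholded("positive").data.astype(bool)
        | hub.thresholded("negative").data.astype(bool)
    )
    rows = []
    for name, roi in rois.items():
        if not roi.grid_compatible(hub.match_r):
            raise ValueError(f"ROI {name!r} is not on the hub map's grid")
        sel = roi.data.astype(bool)
        inter = supra & sel
        peak = float(np.abs(vals[sel]).max()) if sel.any() else np.nan
        rows.append(
            {
                "roi": name,
                "n_overlap_voxels": int(inter.sum()),
                "peak_abs_r_in_roi": peak if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
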
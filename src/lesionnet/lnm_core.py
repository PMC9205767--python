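"""Lesion network mapping: each lesion's functional-connectivity map.

A lesion mask is used as a seed region against a multi-subject resting-state
connectome. For every subject, the mean in-lesion time series is correlated
with every in-brain voxel's series; the correlation map is Fisher
z-transformed; per-subject z-maps are then combined (mean-z by default, a
one-sample t alternative is available) into one *lesion network map* per
lesion.

Voxel order convention: a ``Connectome`` stores each subject as a T x V
matrix where column order is the C-order of the brain mask's nonzero voxels,
matching :func:`lesionnet.volume_io.read_timeseries`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BinaryMask, Volume

__all__ = [
    "Connectome",
    "LesionNetworkMap",
    "extract_seed_timeseries",
    "seed_connectivity_map",
    "fisher_z",
    "lesion_network_map",
    "split_half_reliability",
    "to_vector",
    "to_volume",
]

#: |r| is clipped here before atanh so z stays finite.
R_CLIP = 1.0 - 1e-7


@dataclass
class Connectome:
    """Multi-subject resting-state reference dataset.

    ``subjects`` maps subject id -> T x V time-series matrix over
    ``brain_mask``'s voxel order. ``preprocessing_tag`` records how the
    series were preprocessed upstream (e.g. ``"gsr"`` vs ``"no-gsr"``);
    this package performs no fMRI preprocessing itself.
    """

    subjects: dict[str, np.ndarray]
    brain_mask: BinaryMask
    preprocessing_tag: str = "gsr"

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("connectome has no subjects")
        v = self.n_voxels
        for sid, ts in self.subjects.items():
            ts = np.asarray(ts, dtype=np.float64)
            if ts.ndim != 2 or ts.shape[1] != v:
                raise ValueError(
                    f"subject {sid}: time series shape {ts.shape} incompatible "
                    f"with brain mask ({v} voxels)"
                )
            if ts.shape[0] < 10:
                raise ValueError(f"subject {sid}: fewer than 10 timepoints")
            self.subjects[sid] = ts

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_voxels(self) -> int:
        return self.brain_mask.n_voxels

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects.keys())


@dataclass
class LesionNetworkMap:
    """One lesion's combined connectivity map in Fisher-z units."""

    lesion_id: str
    zmap: Volume
    n_subjects_used: int
    combine: str = "mean_z"

    def zvector(self, brain_mask: BinaryMask) -> np.ndarray:
        return to_vector(self.zmap, brain_mask)


def to_vector(vol: Volume, brain_mask: BinaryMask) -> np.ndarray:
    """Flatten a Volume to the brain mask's V-vector (C-order over ones)."""
    if not vol.grid_compatible(brain_mask):
        raise ValueError("volume not on the brain-mask grid")
    return np.asarray(vol.data, dtype=np.float64)[brain_mask.data > 0]


def to_volume(vec: np.ndarray, brain_mask: BinaryMask, fill: float = np.nan) -> Volume:
    """Unflatten a V-vector to a Volume, ``fill`` outside the brain."""
    vec = np.asarray(vec, dtype=np.float64)
    out = np.full(brain_mask.shape, fill, dtype=np.float64)
    out[brain_mask.data > 0] = vec
    return Volume(out, brain_mask.affine, brain_mask.space)


def extract_seed_timeseries(
    mask: BinaryMask, timeseries: np.ndarray, brain_mask: BinaryMask
) -> np.ndarray:
    """Unweighted mean time series over in-mask, in-brain voxels.

    The seed is the lesion itself: every lesion voxel that falls inside the
    brain mask contributes equally at each timepoint. Lesion voxels outside
    the brain mask are ignored; an empty intersection is an error.
    """
    if not mask.grid_compatible(brain_mask):
        raise ValueError("seed mask not on the connectome grid")
    in_brain = brain_mask.data > 0
    sel = (np.asarray(mask.data) > 0)[in_brain]  # V-length bool
    if not sel.any():
        raise ValueError("seed mask does not intersect the brain mask")
    return np.asarray(timeseries, dtype=np.float64)[:, sel].mean(axis=1)


def seed_connectivity_map(
    seed_ts: np.ndarray, timeseries: np.ndarray, brain_mask: BinaryMask | None = None
) -> np.ndarray:
    """Pearson r of the seed series with every voxel's series (V-vector).

    Series are demeaned per voxel before correlation; nothing else is done
    to them. Voxels with zero temporal variance get r = 0 (not NaN) so group
    models keep full voxel coverage. A constant seed series is an error: it
    carries no connectivity information.
    """
    seed = np.asarray(seed_ts, dtype=np.float64)
    ts = np.asarray(timeseries, dtype=np.float64)
    if seed.shape[0] != ts.shape[0]:
        raise ValueError("seed series length does not match time series")
    seed = seed - seed.mean()
    seed_ss = float(seed @ seed)
    if seed_ss <= 0:
        raise ValueError("seed time series is constant (uninformative seed)")
    x = ts - ts.mean(axis=0, keepdims=True)
    vox_ss = np.einsum("tv,tv->v", x, x)
    num = seed @ x
    denom = np.sqrt(seed_ss * vox_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(vox_ss > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r: np.ndarray | Volume) -> np.ndarray | Volume:
    """Variance-stabilising Fisher transform z = atanh(r).

    |r| is clipped to 1 - 1e-7 first so exact +/-1 stays finite. Accepts a
    plain array or a Volume (NaNs pass through).
    """
    if isinstance(r, Volume):
        return r.with_data(fisher_z(np.asarray(r.data)))
    r = np.asarray(r, dtype=np.float64)
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def lesion_network_map(
    mask: BinaryMask,
    connectome: Connectome,
    lesion_id: str = "",
    combine: str = "mean_z",
) -> LesionNetworkMap:
    """Compute a lesion's network map across all connectome subjects.

    ``combine="mean_z"`` (default) averages the per-subject Fisher-z maps;
    ``combine="tstat"`` returns the per-voxel one-sample t statistic of the
    z-maps against zero. Both are monotonically related when per-voxel
    subject variances are similar. Lesion voxels are retained in the output
    (not blanked); mask downstream if exclusion is wanted.
    """
    if combine not in ("mean_z", "tstat"):
        raise ValueError(f"unknown combine rule {combine!r}")
    bm = connectome.brain_mask
    zsum = np.zeros(connectome.n_voxels)
    zsq = np.zeros(connectome.n_voxels)
    n = 0
    for sid, ts in connectome.subjects.items():
        try:
            seed = extract_seed_timeseries(mask, ts, bm)
            r = seed_connectivity_map(seed, ts, bm)
        except ValueError as err:
            raise ValueError(f"lesion {lesion_id or '<unnamed>'}: {err}") from err
        z = fisher_z(r)
        zsum += z
        zsq += z * z
        n += 1
    mean = zsum / n
    if combine == "mean_z":
        out = mean
    else:
        if n < 2:
            raise ValueError("tstat combination needs >= 2 subjects")
        var = (zsq - n * mean**2) / (n - 1)
        out = mean / np.sqrt(np.maximum(var, 1e-24) / n)
    return LesionNetworkMap(
        lesion_id=lesion_id,
        zmap=to_volume(out, bm),
        n_subjects_used=n,
        combine=combine,
    )


def split_half_reliability(
    connectome: Connectome,
    masks: dict[str, BinaryMask],
    seed: int = 0,
    combine: str = "mean_z",
) -> tuple[dict[str, float], float]:
    """Spatial correlation of lesion maps from two disjoint subject halves.

    Subjects are shuffled deterministically by ``seed`` and split in two;
    each lesion's network map is computed separately on each half and the
    two maps correlated over the brain mask. Returns per-lesion r and the
    cohort mean. Requires >= 4 subjects so each half has >= 2.
    """
    ids = connectome.subject_ids
    if len(ids) < 4:
        raise ValueError("split-half reliability needs >= 4 subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    cut = len(ids) // 2
    halves = [
        Connectome(
            {ids[i]: connectome.subjects[ids[i]] for i in order[:cut]},
            connectome.brain_mask,
            connectome.preprocessing_tag,
        ),
        Connectome(
            {ids[i]: connectome.subjects[ids[i]] for i in order[cut:]},
            connectome.brain_mask,
            connectome.preprocessing_tag,
        ),
    ]
    rel: dict[str, float] = {}
    for lesion_id, mask in masks.items():
        vecs = [
            lesion_network_map(mask, half, lesion_id, combine).zvector(
                connectome.brain_mask
            )
            for half in halves
        ]
        rel[lesion_id] = float(np.corrcoef(vecs[0], vecs[1])[0, 1])
    mean_r = float(np.mean(list(rel.values())))
    return rel, mean_r
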
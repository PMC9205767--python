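"""Volumes, binary masks, and lesion-cohort metadata on a fixed atlas grid.

Every map in the pipeline -- lesion masks, connectivity z-maps, statistic
maps, tract probability maps -- is a :class:`Volume`: a 3D scalar grid plus
a voxel-to-world affine and a space label. All inputs to an analysis must be
*grid-compatible* (same shape, affines equal within a small mm tolerance);
no resampling or registration is performed here, a grid mismatch is a hard
error. Masks never contain NaN; NaN in a statistic map means "outside the
analysis mask".

Cohort metadata travels as a TSV with one row per lesion (columns:
``lesion_id``, ``mask_path``, ``site``, ``outcome``, ``lesion_size_voxels``
plus optional covariates); lesion masks are NIfTI files referenced by path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AFFINE_TOL_MM",
    "OUTCOMES",
    "Volume",
    "BinaryMask",
    "LesionRecord",
    "LesionCohort",
    "read_volume",
    "write_volume",
    "read_timeseries",
    "write_timeseries",
    "mask_tissue_proportion",
    "check_cohort_grid",
]

#: Affine agreement tolerance (mm) for two volumes to share a grid.
AFFINE_TOL_MM = 1e-4

#: Valid smoking-outcome categories, ordered from best to worst outcome.
OUTCOMES = ("remission", "quit_no_remission", "non_quitter")


@dataclass
class Volume:
    """A 3D scalar map with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data:
        3D array. Statistic maps may contain NaN (meaning outside the
        analysis mask); masks may not.
    affine:
        4x4 invertible voxel-to-world transform (NIfTI convention: 0-based
        voxel indices, world coordinates at voxel centers).
    space:
        Free-form grid label, e.g. ``"MNI152-2mm"`` or ``"synthetic-24"``.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"Volume data must be 3D with nonzero extent, got shape {self.data.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3, |det| of the 3x3 affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def grid_compatible(self, other: "Volume", tol: float = AFFINE_TOL_MM) -> bool:
        """True iff shapes are equal and affines agree within ``tol`` mm."""
        return self.shape == other.shape and bool(
            np.all(np.abs(self.affine - other.affine) <= tol)
        )

    def with_data(self, data: np.ndarray, space: str | None = None) -> "Volume":
        """A new Volume on this grid carrying ``data``."""
        return Volume(np.asarray(data), self.affine.copy(), space or self.space)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n,3) voxel indices to (n,3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homog = np.c_[ijk, np.ones(len(ijk))]
        return (homog @ self.affine.T)[:, :3]


class BinaryMask(Volume):
    """A Volume whose values are exactly {0, 1}.

    An all-zero mask is rejected unless ``allow_empty=True`` (some report-only
    operations tolerate empties; seeds and ROIs never do).
    """

    def __init__(
        self,
        data: np.ndarray,
        affine: np.ndarray,
        space: str = "",
        allow_empty: bool = False,
    ) -> None:
        data = np.asarray(data)
        if np.isnan(data.astype(float)).any():
            raise ValueError("masks may not contain NaN")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be 0/1, found {uniq[:5]}")
        super().__init__(data.astype(np.uint8), affine, space)
        if not allow_empty and self.n_voxels == 0:
            raise ValueError("mask is empty (no nonzero voxel)")

    @property
    def n_voxels(self) -> int:
        """Lesion/mask volume in voxels (count of ones)."""
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def indices(self) -> np.ndarray:
        """(n,3) voxel indices of the mask's nonzero voxels."""
        return np.argwhere(self.data > 0)

    @classmethod
    def from_volume(cls, vol: Volume, allow_empty: bool = False) -> "BinaryMask":
        return cls(vol.data, vol.affine, vol.space, allow_empty=allow_empty)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI volume (optionally .nii.gz).

    The affine follows nibabel's sform/qform precedence. A 4D file is
    rejected with a pointer to :func:`read_timeseries`. Trailing singleton
    dimensions (shape ``(x, y, z, 1)``) are squeezed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim == 4:
        raise ValueError(
            f"{path} is 4D; use read_timeseries() for time-series volumes"
        )
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D, expected 3D")
    return Volume(data, img.affine, space="")


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a Volume as NIfTI-1. Integer arrays round-trip bit-exactly."""
    path = Path(path)
    data = vol.data
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    return path


def read_timeseries(path: str | Path, brain_mask: BinaryMask) -> np.ndarray:
    """Read a 4D NIfTI as a T x V matrix over ``brain_mask``'s voxel order.

    Voxel order is C-order over the mask's nonzero voxels (the order
    ``data[mask > 0]`` produces), the convention used throughout the package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}D, expected 4D time series")
    if data.shape[:3] != brain_mask.shape:
        raise ValueError(
            f"time series grid {data.shape[:3]} != brain mask grid {brain_mask.shape}"
        )
    sel = brain_mask.data > 0
    return data[sel, :].T.astype(np.float64)  # (T, V)


def write_timeseries(ts: np.ndarray, brain_mask: BinaryMask, path: str | Path) -> Path:
    """Write a T x V matrix back to a 4D NIfTI over ``brain_mask``."""
    ts = np.asarray(ts, dtype=np.float64)
    sel = brain_mask.data > 0
    if ts.shape[1] != int(sel.sum()):
        raise ValueError("time-series width does not match mask voxel count")
    out = np.zeros(brain_mask.shape + (ts.shape[0],), dtype=np.float32)
    out[sel, :] = ts.T
    nib.save(nib.Nifti1Image(out, brain_mask.affine), str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Mask utilities


def mask_tissue_proportion(lesion: BinaryMask, tissue_prob: Volume) -> float:
    """Mean tissue probability over the lesion's voxels.

    Used to build the gray/white-matter-proportion covariate for robustness
    models. ``tissue_prob`` must hold probabilities in [0, 1] on the lesion's
    grid.
    """
    if not lesion.grid_compatible(tissue_prob):
        raise ValueError("lesion and tissue map are not grid-compatible")
    probs = np.asarray(tissue_prob.data, dtype=float)
    if np.nanmin(probs) < -1e-9 or np.nanmax(probs) > 1 + 1e-9:
        raise ValueError("tissue probabilities must lie in [0, 1]")
    if lesion.n_voxels == 0:
        raise ValueError("empty lesion mask")
    return float(probs[lesion.data > 0].mean())


# ---------------------------------------------------------------------------
# Cohort metadata


@dataclass
class LesionRecord:
    """One patient: lesion mask, study site, smoking outcome, covariates."""

    lesion_id: str
    site: str
    outcome: str
    mask: BinaryMask | None = None
    mask_path: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"outcome {self.outcome!r} not in {OUTCOMES} (lesion {self.lesion_id})"
            )

    @property
    def lesion_size_voxels(self) -> int:
        if "lesion_size_voxels" in self.covariates:
            return int(self.covariates["lesion_size_voxels"])
        if self.mask is not None:
            return self.mask.n_voxels
        raise ValueError(f"lesion {self.lesion_id}: no mask loaded and no size recorded")


@dataclass
class LesionCohort:
    """An ordered collection of :class:`LesionRecord`.

    Row order is the canonical lesion order for design matrices and map
    stacks downstream; never reorder silently.
    """

    records: list[LesionRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lesion_ids(self) -> list[str]:
        return [r.lesion_id for r in self.records]

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self.records])

    @property
    def sites(self) -> np.ndarray:
        return np.array([r.site for r in self.records])

    def subset(self, keep: np.ndarray) -> "LesionCohort":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return LesionCohort([self.records[int(i)] for i in keep])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "lesion_id": r.lesion_id,
                "mask_path": r.mask_path or "",
                "site": r.site,
                "outcome": r.outcome,
                "lesion_size_voxels": r.lesion_size_voxels,
            }
            for k, v in r.covariates.items():
                if k != "lesion_size_voxels":
                    row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> Path:
        self.to_frame().to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path, load_masks: bool = False) -> "LesionCohort":
        df = pd.read_csv(path, sep="\t", dtype={"lesion_id": str, "site": str})
        required = {"lesion_id", "mask_path", "site", "outcome"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort TSV missing columns: {sorted(missing)}")
        base = Path(path).parent
        records = []
        for _, row in df.iterrows():
            cov_cols = [
                c for c in df.columns if c not in ("lesion_id", "mask_path", "site", "outcome")
            ]
            covs = {c: float(row[c]) for c in cov_cols if pd.notna(row[c])}
            mask = None
            mask_path = str(row["mask_path"]) if row["mask_path"] else None
            if load_masks and mask_path:
                p = Path(mask_path)
                if not p.is_absolute():
                    p = base / p
                mask = BinaryMask.from_volume(read_volume(p))
            records.append(
                LesionRecord(
                    lesion_id=str(row["lesion_id"]),
                    site=str(row["site"]),
                    outcome=str(row["outcome"]),
                    mask=mask,
                    mask_path=mask_path,
                    covariates=covs,
                )
            )
        return cls(records)


def check_cohort_grid(
    cohort: LesionCohort, reference: Volume, tol: float = AFFINE_TOL_MM
) -> list[tuple[str, str]]:
    """Report lesions not grid-compatible with ``reference``.

    Returns a list of ``(lesion_id, reason)``; empty means all masks share
    the reference grid. Report-only: callers decide whether to abort (the
    pipeline refuses mixed grids).
    """
    problems: list[tuple[str, str]] = []
    for rec in cohort:
        if rec.mask is None:
            problems.append((rec.lesion_id, "mask not loaded"))
            continue
        if rec.mask.shape != reference.shape:
            problems.append(
                (rec.lesion_id, f"shape {rec.mask.shape} != {reference.shape}")
            )
        elif not rec.mask.grid_compatible(reference, tol=tol):
            problems.append((rec.lesion_id, "affine mismatch beyond tolerance"))
    return problems
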
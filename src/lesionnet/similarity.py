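"""Spatial-correlation comparisons between voxel-wise maps.

Reproducibility (do two cohorts' contrast maps agree?), cross-cohort
prediction (do per-lesion similarity scores track outcome?), within-group
map similarity, and specificity (does the reference network match the
target behavioral variable better than a battery of others?). All
similarity is computed on unthresholded statistic maps within the analysis
brain mask; permutation nulls shuffle outcome labels or behavioral scores,
never voxels, so spatial autocorrelation is preserved under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lnm_core import LesionNetworkMap, to_vector
from .map_stats import DesignMatrix, RankTestResult, _contrast_t, mann_whitney, stack_maps
from .volume_io import BinaryMask, Volume

__all__ = [
    "SimilarityResult",
    "CohortMaps",
    "spatial_correlation",
    "map_similarity_permutation",
    "score_lesions_against_map",
    "within_group_pairwise_similarity",
    "specificity_ranking",
]


@dataclass
class SimilarityResult:
    """Spatial correlation with its label-permutation null."""

    r: float
    p_perm: float
    n_perm: int
    null_rs: np.ndarray


@dataclass
class CohortMaps:
    """One cohort's map stack and design, ready for contrast permutation."""

    Y: np.ndarray  # N x V Fisher-z maps
    design: DesignMatrix

    def contrast_map(self, outcome: np.ndarray | None = None) -> np.ndarray:
        design = self.design if outcome is None else self.design.with_outcome(outcome)
        return _contrast_t(design.matrix, design.contrast, self.Y)


def _finite_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ok = np.isfinite(a) & np.isfinite(b)
    return a[ok], b[ok]


def spatial_correlation(
    mapA: Volume | np.ndarray,
    mapB: Volume | np.ndarray,
    mask: BinaryMask | None = None,
) -> float:
    """Pearson r between two maps over in-mask voxels with finite values.

    Accepts Volumes (with a mask) or already-flattened vectors. Requires at
    least 10 jointly finite voxels and nonzero variance in both maps.
    """
    if isinstance(mapA, Volume):
        if mask is None:
            raise ValueError("a mask is required when passing Volumes")
        a = to_vector(mapA, mask)
        b = to_vector(mapB, mask)
    else:
        a = np.asarray(mapA, dtype=float)
        b = np.asarray(mapB, dtype=float)
    a, b = _finite_pair(a, b)
    if a.size < 10:
        raise ValueError("fewer than 10 jointly finite in-mask voxels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within the mask")
    return float(np.corrcoef(a, b)[0, 1])


def _stratified_permutation(
    values: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute ``values`` within each stratum (site) independently."""
    out = values.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        out[idx] = values[idx[rng.permutation(len(idx))]]
    return out


def map_similarity_permutation(
    cohortA: CohortMaps,
    cohortB: CohortMaps,
    n_perm: int = 1000,
    seed: int = 0,
) -> SimilarityResult:
    """Cross-cohort reproducibility of the outcome contrast map.

    The observed statistic is the spatial r between the two cohorts'
    unthresholded contrast t-maps. The null permutes each cohort's outcome
    labels within site strata, recomputes both maps, and correlates;
    one-sided p = (1 + #{null r >= observed}) / (n_perm + 1).
    """
    for cm in (cohortA, cohortB):
        out = cm.design.frame["outcome"].to_numpy()
        if len(np.unique(out)) < 2:
            raise ValueError("a cohort has no outcome variation to permute")
    rng = np.random.default_rng(seed)
    mapA = cohortA.contrast_map()
    mapB = cohortB.contrast_map()
    r_obs = spatial_correlation(mapA, mapB)
    null = np.empty(n_perm)
    outA = cohortA.design.frame["outcome"].to_numpy()
    outB = cohortB.design.frame["outcome"].to_numpy()
    for b in range(n_perm):
        pa = _stratified_permutation(outA, cohortA.design.site, rng)
        pb = _stratified_permutation(outB, cohortB.design.site, rng)
        null[b] = spatial_correlation(cohortA.contrast_map(pa), cohortB.contrast_map(pb))
    p = (1.0 + np.sum(null >= r_obs - 1e-12)) / (n_perm + 1.0)
    return SimilarityResult(r=r_obs, p_perm=float(p), n_perm=n_perm, null_rs=null)


def score_lesions_against_map(
    maps: list[LesionNetworkMap] | np.ndarray,
    reference: Volume | np.ndarray,
    brain_mask: BinaryMask,
) -> np.ndarray:
    """Per-lesion spatial correlation of its network map with a reference.

    The per-lesion scores feed cross-cohort outcome prediction and
    case-report scoring; group separation is then tested with
    :func:`lesionnet.map_stats.mann_whitney`.
    """
    Y = stack_maps(maps, brain_mask)
    ref = (
        to_vector(reference, brain_mask)
        if isinstance(reference, Volume)
        else np.asarray(reference, dtype=float)
    )
    return np.array([spatial_correlation(y, ref) for y in Y])


def within_group_pairwise_similarity(
    maps: list[LesionNetworkMap] | np.ndarray,
    groups: np.ndarray,
    brain_mask: BinaryMask,
    group_order: tuple | None = None,
) -> tuple[RankTestResult, dict]:
    """Are maps within group 1 more alike than maps within group 2?

    All pairwise spatial correlations within each group are compared with a
    Mann-Whitney U test (first sample = first group's pairwise set). Note
    the pairwise correlations are not independent observations; the test is
    descriptive in that respect.
    """
    groups = np.asarray(groups)
    levels = list(group_order) if group_order is not None else list(np.unique(groups))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    Y = stack_maps(maps, brain_mask)
    pair_sets = {}
    for lev in levels:
        sub = Y[groups == lev]
        if sub.shape[0] < 3:
            raise ValueError(f"group {lev!r} has fewer than 3 lesions")
        C = np.corrcoef(sub)
        iu = np.triu_indices(sub.shape[0], k=1)
        pair_sets[lev] = C[iu]
    res = mann_whitney(pair_sets[levels[0]], pair_sets[levels[1]])
    return res, pair_sets


def specificity_ranking(
    reference: Volume | np.ndarray,
    scores: pd.DataFrame,
    maps: list[LesionNetworkMap] | np.ndarray,
    brain_mask: BinaryMask,
    target: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank behavioral variables by how well their network map matches a reference.

    For each continuous variable, a voxel-wise correlation map (per-voxel
    Pearson r between lesion connectivity and the score, across lesions) is
    computed and spatially correlated with the reference map. The designated
    ``target`` variable additionally gets a one-sided permutation p by
    shuffling its scores; other rows report r and descriptive rank only.
    Returns a DataFrame sorted by descending r with columns
    variable / r / rank / is_target / p_perm.
    """
    if scores.shape[1] < 2:
        raise ValueError("need at least 2 variables for a specificity ranking")
    if target not in scores.columns:
        raise ValueError(f"target variable {target!r} not in score table")
    Y = stack_maps(maps, brain_mask)
    if Y.shape[0] != len(scores):
        raise ValueError("score rows do not match number of maps")
    ref = (
        to_vector(reference, brain_mask)
        if isinstance(reference, Volume)
        else np.asarray(reference, dtype=float)
    )
    Yc = Y - Y.mean(axis=0, keepdims=True)
    Ynorm = np.sqrt(np.einsum("nv,nv->v", Yc, Yc))

    def corr_map(score: np.ndarray) -> np.ndarray:
        s = score - score.mean()
        sn = np.linalg.norm(s)
        if sn == 0:
            raise ValueError("constant behavioral variable")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(Ynorm > 0, (s @ Yc) / (sn * Ynorm), 0.0)

    rows = []
    for var in scores.columns:
        rv = spatial_correlation(corr_map(scores[var].to_numpy(dtype=float)), ref)
        rows.append({"variable": var, "r": rv, "is_target": var == target})
    table = pd.DataFrame(rows).sort_values("r", ascending=False).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)

    rng = np.random.default_rng(seed)
    tscore = scores[target].to_numpy(dtype=float)
    r_obs = float(table.loc[table.is_target, "r"].iloc[0])
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = spatial_correlation(corr_map(rng.permutation(tscore)), ref)
    p = (1.0 + np.sum(null >= r_obs - 1e-12)) / (n_perm + 1.0)
    table["p_perm"] = np.where(table["is_target"], p, np.nan)
    return table
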
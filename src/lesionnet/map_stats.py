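"""Voxel-wise inference on lesion network maps.

The group model is an ordinary-least-squares GLM at each voxel relating
lesion connectivity (Fisher-z) to clinical outcome, with study site and
optional covariates as nuisance regressors. Spatially extended signal is
enhanced with threshold-free cluster enhancement (TFCE) and family-wise
error is controlled by the permutation distribution of the maximum TFCE
statistic (Freedman-Lane residual permutation under the nuisance-only
model, identity permutation always included).

The same permutation engine drives voxel-lesion-symptom mapping (VLSM,
where the voxel-wise regressor is lesion presence/absence) and the scalar
tract/disconnectome tests in :mod:`lesionnet.structural`.

Outcome coding: remission = 1, non_quitter = 0, and the intermediate
quit-without-remission category = 0.5 on the same axis by default (it can
instead be coded as a separate dummy column), so the tested contrast is the
remission-versus-non-quitter axis while the middle group adds spatial
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .lnm_core import LesionNetworkMap, to_volume
from .volume_io import BinaryMask, LesionCohort, Volume

__all__ = [
    "DesignMatrix",
    "TFCEParams",
    "ContrastMap",
    "InteractionResult",
    "RankTestResult",
    "build_design",
    "fit_voxelwise_glm",
    "contrast_effect_map",
    "tfce_enhance",
    "permutation_fwe",
    "vlsm",
    "roi_interaction_test",
    "mann_whitney",
    "stack_maps",
]

SIDEDNESS = ("two-sided", "positive", "negative")


@dataclass
class DesignMatrix:
    """Design for the voxel-wise GLM, rows in cohort order.

    ``frame`` holds the named columns (intercept, outcome, site dummies,
    covariates); ``contrast`` is a weight vector over those columns;
    ``site`` keeps the raw per-row site labels for stratified permutation.
    """

    frame: pd.DataFrame
    contrast: np.ndarray
    site: np.ndarray

    def __post_init__(self) -> None:
        self.contrast = np.asarray(self.contrast, dtype=float)
        X = self.matrix
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if self.contrast.shape != (X.shape[1],):
            raise ValueError("contrast length does not match design columns")

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def outcome_index(self) -> int:
        return int(self.frame.columns.get_loc("outcome"))

    def with_outcome(self, outcome: np.ndarray) -> "DesignMatrix":
        frame = self.frame.copy()
        frame["outcome"] = np.asarray(outcome, dtype=float)
        return DesignMatrix(frame, self.contrast.copy(), self.site)


OUTCOME_CODES_LINEAR = {"remission": 1.0, "quit_no_remission": 0.5, "non_quitter": 0.0}


def build_design(
    cohort: LesionCohort,
    covariates: tuple[str, ...] = (),
    outcome_coding: str = "linear",
) -> DesignMatrix:
    """Design matrix from cohort metadata.

    ``outcome_coding="linear"`` places the three outcome categories on one
    axis (1 / 0.5 / 0); ``"dummy"`` instead adds a separate indicator column
    for the intermediate group. Site enters as treatment-coded dummies
    (first site is reference). ``covariates`` name numeric columns of the
    lesion records (e.g. ``lesion_size_voxels``, ``age``, ``gm_proportion``).
    The contrast selects the outcome column.
    """
    if outcome_coding not in ("linear", "dummy"):
        raise ValueError("outcome_coding must be 'linear' or 'dummy'")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    out = cohort.outcomes
    if outcome_coding == "linear":
        cols["outcome"] = np.array([OUTCOME_CODES_LINEAR[o] for o in out])
    else:
        cols["outcome"] = (out == "remission").astype(float)
        cols["quit_no_remission"] = (out == "quit_no_remission").astype(float)
    sites = cohort.sites
    for s in sorted(set(sites))[1:]:
        cols[f"site_{s}"] = (sites == s).astype(float)
    for cov in covariates:
        vals = []
        for rec in cohort:
            if cov == "lesion_size_voxels":
                vals.append(float(rec.lesion_size_voxels))
            elif cov in rec.covariates:
                vals.append(float(rec.covariates[cov]))
            else:
                raise ValueError(f"lesion {rec.lesion_id} lacks covariate {cov!r}")
        cols[cov] = np.array(vals)
    frame = pd.DataFrame(cols)
    contrast = np.zeros(frame.shape[1])
    contrast[frame.columns.get_loc("outcome")] = 1.0
    return DesignMatrix(frame, contrast, sites)


@dataclass
class TFCEParams:
    """TFCE parameters: FSL defaults E=0.5, H=2, dh=max/100, 26-connectivity."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # None -> max statistic / n_steps
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class ContrastMap:
    """Voxel-wise statistic map with uncorrected and FWE-corrected p-maps."""

    stat: Volume
    p_unc: Volume
    p_fwe: Volume
    contrast_label: str = ""
    n_perm: int = 0
    sidedness: str = "two-sided"

    def significant_mask(self, alpha: float = 0.05) -> BinaryMask:
        sig = np.nan_to_num(np.asarray(self.p_fwe.data), nan=1.0) < alpha
        return BinaryMask(
            sig.astype(np.uint8), self.stat.affine, self.stat.space, allow_empty=True
        )


@dataclass
class InteractionResult:
    F: float
    df: tuple[int, int]
    p: float


@dataclass
class RankTestResult:
    U: float
    p: float
    n1: int
    n2: int


def stack_maps(
    maps: list[LesionNetworkMap] | np.ndarray, brain_mask: BinaryMask
) -> np.ndarray:
    """N x V matrix of z-values from a list of lesion network maps."""
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=np.float64)
    return np.stack([m.zvector(brain_mask) for m in maps])


# ---------------------------------------------------------------------------
# OLS contrast machinery (vectorised over voxels)


def _contrast_t(X: np.ndarray, c: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS t statistic for contrast c at every column of Y."""
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("nv,nv->v", resid, resid) / dof
    cvar = float(c @ pinv @ pinv.T @ c)  # c' (X'X)^-1 c
    denom = np.sqrt(np.maximum(sigma2 * cvar, 1e-300))
    t = (c @ beta) / denom
    # voxels whose residual variance is numerically zero (constant data up
    # to rounding) carry no evidence either way: define t = 0 there
    degenerate = sigma2 <= 1e-24 * (Y.var(axis=0) + 1.0)
    t[degenerate] = 0.0
    return t


def fit_voxelwise_glm(
    maps: list[LesionNetworkMap] | np.ndarray,
    design: DesignMatrix,
    brain_mask: BinaryMask,
) -> Volume:
    """Per-voxel OLS t statistic for the design's contrast.

    Requires at least two lesions at each extreme of the contrasted outcome
    axis so the contrast is identified by data, not extrapolation.
    """
    Y = stack_maps(maps, brain_mask)
    if Y.shape[0] != design.n:
        raise ValueError("number of maps does not match design rows")
    outcome = design.frame["outcome"].to_numpy()
    if (outcome == outcome.max()).sum() < 2 or (outcome == outcome.min()).sum() < 2:
        raise ValueError("fewer than 2 lesions at an extreme of the outcome axis")
    t = _contrast_t(design.matrix, design.contrast, Y)
    return to_volume(t, brain_mask)


def contrast_effect_map(
    maps: list[LesionNetworkMap] | np.ndarray,
    design: DesignMatrix,
    brain_mask: BinaryMask,
) -> Volume:
    """Per-voxel contrast effect c'beta-hat (z units).

    The amplitude estimate of the outcome-associated network: the
    covariate-adjusted group difference in Fisher-z connectivity at each
    voxel. Unlike the t map it is not renormalised by per-voxel residual
    variance, so it is the map to compare against a planted or reference
    network's amplitude; the t map is the evidence map for thresholding.
    """
    Y = stack_maps(maps, brain_mask)
    if Y.shape[0] != design.n:
        raise ValueError("number of maps does not match design rows")
    beta = np.linalg.pinv(design.matrix) @ Y
    return to_volume(design.contrast @ beta, brain_mask)


# ---------------------------------------------------------------------------
# TFCE


try:  # optional union-find fast path; the scipy sweep below is the fallback
    from ._tfce_fast import tfce_sweep as _tfce_sweep_fast
except Exception:  # pragma: no cover - numba missing
    _tfce_sweep_fast = None


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                order = abs(di) + abs(dj) + abs(dk)
                if order == 0:
                    continue
                if (connectivity == 6 and order > 1) or (connectivity == 18 and order > 2):
                    continue
                offs.append((di, dj, dk))
    return np.array(offs, dtype=np.int64)


def _tfce_one_tail(x: np.ndarray, params: TFCEParams) -> np.ndarray:
    """TFCE of a nonnegative map: sum_h extent(h)^E * h^H * dh.

    Thresholds h = dh, 2dh, ... <= max; extent is the voxel count of the
    26- (or 6-/18-) connected suprathreshold cluster containing the voxel.
    Uses a sorted union-find sweep when numba is importable, else a
    per-threshold connected-component labeling; the two are numerically
    identical (same thresholds, integer extents).
    """
    hmax = float(x.max(initial=0.0))
    if hmax <= 0:
        return np.zeros_like(x)
    dh = params.dh if params.dh is not None else hmax / params.n_steps
    n_steps = int((hmax + 1e-12) / dh)
    if _tfce_sweep_fast is not None:
        return _tfce_sweep_fast(
            np.ascontiguousarray(x, dtype=np.float64),
            _neighbor_offsets(params.connectivity),
            params.E, params.H, dh, n_steps,
        )
    out = np.zeros_like(x)
    structure = params.structure
    for k in range(1, n_steps + 1):
        h = k * dh
        sup = x >= h - 1e-9 * dh
        labels, nlab = ndimage.label(sup, structure=structure)
        if nlab == 0:
            break
        sizes = np.bincount(labels.ravel())
        contrib = sizes.astype(np.float64) ** params.E * (h**params.H) * dh
        contrib[0] = 0.0
        out += contrib[labels]
    return out


def tfce_enhance(stat: Volume | np.ndarray, params: TFCEParams | None = None) -> Volume | np.ndarray:
    """Threshold-free cluster enhancement, both tails.

    The negative tail is enhanced by applying the positive-tail sweep to the
    negated map and negating the result; output keeps the input's sign
    structure. NaNs (outside the analysis mask) are treated as 0 and
    restored afterwards. An all-zero map returns all zeros.
    """
    params = params or TFCEParams()
    vol = isinstance(stat, Volume)
    arr = np.asarray(stat.data if vol else stat, dtype=np.float64)
    nanmask = np.isnan(arr)
    x = np.where(nanmask, 0.0, arr)
    enhanced = _tfce_one_tail(np.where(x > 0, x, 0.0), params) - _tfce_one_tail(
        np.where(x < 0, -x, 0.0), params
    )
    enhanced[nanmask] = np.nan
    return stat.with_data(enhanced) if vol else enhanced


# ---------------------------------------------------------------------------
# Freedman-Lane permutation FWE


def _freedman_lane_parts(X: np.ndarray, c: np.ndarray):
    """Split design into contrast and nuisance parts; nuisance projectors."""
    active = c != 0
    Z = X[:, ~active]
    if Z.shape[1] == 0:
        Hz = np.zeros((X.shape[0], X.shape[0]))
    else:
        Hz = Z @ np.linalg.pinv(Z)
    Rz = np.eye(X.shape[0]) - Hz
    return Hz, Rz


def _tail_stat(t: np.ndarray, sidedness: str) -> np.ndarray:
    if sidedness == "two-sided":
        return np.abs(t)
    if sidedness == "positive":
        return t
    if sidedness == "negative":
        return -t
    raise ValueError(f"sidedness must be one of {SIDEDNESS}")


def permutation_fwe(
    maps: list[LesionNetworkMap] | np.ndarray,
    design: DesignMatrix,
    brain_mask: BinaryMask,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    sidedness: str = "two-sided",
    contrast_label: str = "outcome",
    voxel_subset: np.ndarray | None = None,
    _regressor_matrix: np.ndarray | None = None,
) -> ContrastMap:
    """TFCE + max-statistic permutation FWE for the design's contrast.

    Freedman-Lane scheme: residuals of the nuisance-only model are permuted
    (identity permutation always included), the full model is refit, and the
    maximum TFCE statistic over the analysis mask builds the null. Voxel-wise
    ``p_unc`` comes from each voxel's own permutation distribution of the t
    statistic; ``p_fwe`` compares observed TFCE against the max-TFCE null, so
    every p respects the 1/(n_perm+1) floor.

    ``voxel_subset`` restricts the analysis (and the max statistic) to a
    boolean V-vector of voxels, used by VLSM's coverage threshold.
    ``_regressor_matrix`` (internal) supplies a per-voxel regressor for VLSM.
    """
    params = params or TFCEParams()
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable FWE estimate")
    Y = stack_maps(maps, brain_mask)
    X = design.matrix
    c = design.contrast
    V = Y.shape[1]
    sel = np.ones(V, dtype=bool) if voxel_subset is None else np.asarray(voxel_subset)

    rng = np.random.default_rng(seed)
    in_brain = brain_mask.data > 0

    def t_stat(Ystar: np.ndarray) -> np.ndarray:
        if _regressor_matrix is None:
            return _contrast_t(X, c, Ystar[:, sel])
        return _vlsm_t(Ystar, _regressor_matrix[:, sel], X, c)

    def tfce_of(tvec: np.ndarray) -> np.ndarray:
        full = np.zeros(V)
        full[sel] = tvec
        vol3 = np.zeros(brain_mask.shape)
        vol3[in_brain] = full
        enh = tfce_enhance(vol3, params)
        return enh[in_brain][sel]

    Hz, Rz = _freedman_lane_parts(X, c)
    if _regressor_matrix is None:
        fitted_nuis = Hz @ Y
        resid_nuis = Rz @ Y
    else:
        # VLSM permutes the (residualised) outcome, not the maps
        fitted_nuis = resid_nuis = None

    t_obs = t_stat(Y)
    signed_obs = _tail_stat(t_obs, sidedness)
    tfce_obs = _tail_stat(tfce_of(t_obs), sidedness)

    n = design.n
    exceed_unc = np.zeros(sel.sum())
    exceed_fwe = np.zeros(sel.sum())
    for b in range(n_perm + 1):
        perm = np.arange(n) if b == 0 else rng.permutation(n)
        if _regressor_matrix is None:
            Ystar = fitted_nuis + resid_nuis[perm]
            t_b = t_stat(Ystar)
        else:
            t_b = _vlsm_t_permuted(Y, _regressor_matrix[:, sel], X, c, perm)
        tail_t = _tail_stat(t_b, sidedness)
        exceed_unc += tail_t >= signed_obs - 1e-12
        tfce_b = _tail_stat(tfce_of(t_b), sidedness)
        exceed_fwe += tfce_b.max() >= tfce_obs - 1e-12
    denom = n_perm + 1
    p_unc = exceed_unc / denom
    p_fwe = exceed_fwe / denom

    def expand(v: np.ndarray, fill: float = np.nan) -> Volume:
        full = np.full(V, fill)
        full[sel] = v
        return to_volume(full, brain_mask)

    return ContrastMap(
        stat=expand(t_obs),
        p_unc=expand(p_unc),
        p_fwe=expand(p_fwe),
        contrast_label=contrast_label,
        n_perm=n_perm,
        sidedness=sidedness,
    )


# ---------------------------------------------------------------------------
# VLSM


def _vlsm_t(y2d: np.ndarray, lesmat: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """t of the per-voxel lesion-presence regressor predicting the outcome.

    By Frisch-Waugh, the t for lesion status adjusting nuisance Z equals the
    correlation of nuisance-residualised outcome with nuisance-residualised
    lesion status, scaled by sqrt(df / (1 - r^2)).
    """
    outcome = X[:, c != 0]
    if outcome.shape[1] != 1:
        raise ValueError("VLSM needs a single outcome column in the contrast")
    Z = X[:, c == 0]
    Rz = np.eye(X.shape[0]) - Z @ np.linalg.pinv(Z)
    ry = (Rz @ outcome).ravel()
    RX = Rz @ lesmat
    return _partial_corr_t(ry, RX, dof=X.shape[0] - Z.shape[1] - 1)


def _vlsm_t_permuted(
    y2d: np.ndarray, lesmat: np.ndarray, X: np.ndarray, c: np.ndarray, perm: np.ndarray
) -> np.ndarray:
    outcome = X[:, c != 0]
    Z = X[:, c == 0]
    Rz = np.eye(X.shape[0]) - Z @ np.linalg.pinv(Z)
    ry = (Rz @ outcome).ravel()[perm]  # Freedman-Lane on the outcome residuals
    RX = Rz @ lesmat
    return _partial_corr_t(ry, RX, dof=X.shape[0] - Z.shape[1] - 1)


def _partial_corr_t(ry: np.ndarray, RX: np.ndarray, dof: int) -> np.ndarray:
    ry = ry - ry.mean()
    RXc = RX - RX.mean(axis=0, keepdims=True)
    num = ry @ RXc
    den = np.sqrt(np.maximum((ry @ ry) * np.einsum("nv,nv->v", RXc, RXc), 1e-300))
    r = np.clip(num / den, -0.999999, 0.999999)
    return r * np.sqrt(dof / (1.0 - r**2))


def vlsm(
    cohort: LesionCohort,
    design: DesignMatrix,
    brain_mask: BinaryMask,
    min_lesions_per_voxel: int = 4,
    params: TFCEParams | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    sidedness: str = "two-sided",
) -> ContrastMap:
    """Voxel-lesion-symptom mapping: lesion presence vs outcome, per voxel.

    At every voxel covered by at least ``min_lesions_per_voxel`` lesions
    (and spared by at least that many), the binary lesion-status regressor
    is tested against the outcome with the design's nuisance columns
    (typically site and lesion size) adjusted; inference uses the same
    TFCE + max-statistic permutation engine as the connectivity contrast.
    Excluded voxels carry NaN in all output maps.
    """
    sel3 = brain_mask.data > 0
    lesmat = np.stack(
        [np.asarray(rec.mask.data)[sel3].astype(float) for rec in cohort]
    )  # N x V
    n = len(cohort)
    coverage = lesmat.sum(axis=0)
    subset = (coverage >= min_lesions_per_voxel) & (coverage <= n - min_lesions_per_voxel)
    if not subset.any():
        raise ValueError(
            f"no voxel is lesioned in >= {min_lesions_per_voxel} and spared in "
            f">= {min_lesions_per_voxel} patients"
        )
    return permutation_fwe(
        np.zeros_like(lesmat),
        design,
        brain_mask,
        params=params,
        n_perm=n_perm,
        seed=seed,
        sidedness=sidedness,
        contrast_label="vlsm",
        voxel_subset=subset,
        _regressor_matrix=lesmat,
    )


# ---------------------------------------------------------------------------
# ROI interaction and rank test


def roi_interaction_test(
    maps: list[LesionNetworkMap] | np.ndarray,
    roiA: BinaryMask,
    roiB: BinaryMask,
    groups: np.ndarray,
    brain_mask: BinaryMask,
) -> InteractionResult:
    """2x2 mixed-design ROI x group interaction on mean ROI connectivity.

    Per lesion, mean Fisher-z within each ROI; the interaction of a
    two-level between factor (group) with a two-level within factor (ROI)
    reduces algebraically to the squared pooled two-sample t on the
    within-lesion difference zA - zB, giving F with df (1, n - 2). This is
    the test behind the dorsal-versus-ventral striatum dissociation.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("roi_interaction_test needs exactly two groups")
    if roiA.n_voxels == 0 or roiB.n_voxels == 0:
        raise ValueError("empty ROI")
    Y = stack_maps(maps, brain_mask)
    sel3 = brain_mask.data > 0
    a_idx = np.asarray(roiA.data)[sel3] > 0
    b_idx = np.asarray(roiB.data)[sel3] > 0
    if not a_idx.any() or not b_idx.any():
        raise ValueError("an ROI does not intersect the brain mask")
    d = Y[:, a_idx].mean(axis=1) - Y[:, b_idx].mean(axis=1)
    d1, d2 = d[groups == levels[0]], d[groups == levels[1]]
    n1, n2 = len(d1), len(d2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 lesions")
    sp2 = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (n1 + n2 - 2)
    t = (d1.mean() - d2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)) if sp2 > 0 else 0.0
    F = float(t**2)
    df = (1, n1 + n2 - 2)
    p = float(stats.f.sf(F, *df))
    return InteractionResult(F=F, df=df, p=p)


def mann_whitney(x, y, alternative: str = "two-sided") -> RankTestResult:
    """Mann-Whitney U for the first sample, exact when feasible.

    U counts pairs (x_i > y_j) plus half-ties. The p-value uses exact
    enumeration when n1*n2 <= 400 and the data are tie-free, otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) * len(y) <= 400 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return RankTestResult(U=float(res.statistic), p=float(res.pvalue), n1=len(x), n2=len(y))
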
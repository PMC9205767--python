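"""GLM contrasts, TFCE, permutation FWE, VLSM, ROI interaction, U test."""

import numpy as np
import pandas as pd
import pytest

from lesionnet.lnm_core import to_vector, to_volume
from lesionnet.map_stats import (
    DesignMatrix,
    TFCEParams,
    _contrast_t,
    build_design,
    contrast_effect_map,
    fit_voxelwise_glm,
    mann_whitney,
    permutation_fwe,
    roi_interaction_test,
    tfce_enhance,
    vlsm,
)
from lesionnet.synthetic_data import ellipsoid_brain_mask, spherical_lesion
from lesionnet.volume_io import BinaryMask, LesionCohort, LesionRecord

from oracles import mann_whitney_u, ols_contrast_t, tfce_brute


# ---------------------------------------------------------------------------
# Design + GLM


def _design_from_arrays(outcome, site=None, extra=None):
    n = len(outcome)
    cols = {"intercept": np.ones(n), "outcome": np.asarray(outcome, float)}
    if site is not None:
        site = np.asarray(site)
        for s in sorted(set(site))[1:]:
            cols[f"site_{s}"] = (site == s).astype(float)
    else:
        site = np.array(["A"] * n)
    if extra is not None:
        for k, v in extra.items():
            cols[k] = np.asarray(v, float)
    frame = pd.DataFrame(cols)
    c = np.zeros(frame.shape[1])
    c[1] = 1.0
    return DesignMatrix(frame, c, site)


def test_build_design_codings_and_rank():
    recs = [
        LesionRecord(f"l{i}", site, out, covariates={"lesion_size_voxels": 10 + i})
        for i, (site, out) in enumerate(
            [("A", "remission"), ("A", "non_quitter"), ("B", "quit_no_remission"),
             ("B", "remission"), ("A", "non_quitter"), ("B", "non_quitter")]
        )
    ]
    cohort = LesionCohort(recs)
    d = build_design(cohort, covariates=("lesion_size_voxels",))
    assert list(d.frame.columns) == ["intercept", "outcome", "site_B", "lesion_size_voxels"]
    assert list(d.frame["outcome"]) == [1.0, 0.0, 0.5, 1.0, 0.0, 0.0]
    d2 = build_design(cohort, outcome_coding="dummy")
    assert "quit_no_remission" in d2.frame.columns
    assert list(d2.frame["outcome"]) == [1.0, 0.0, 0.0, 1.0, 0.0, 0.0]


def test_glm_toy_matches_normal_equations_oracle(rng):
    """2-voxel, 6-lesion toy vs an independently coded OLS oracle."""
    bm = BinaryMask(np.ones((2, 1, 1)), np.eye(4))
    outcome = [1, 1, 0.5, 0, 0, 0]
    size = [3, 9, 4, 8, 2, 6]
    d = _design_from_arrays(outcome, site=["A", "B", "A", "B", "A", "B"],
                            extra={"size": size})
    Y = rng.standard_normal((6, 2))
    t = to_vector(fit_voxelwise_glm(Y, d, bm), bm)
    sm = pytest.importorskip("statsmodels.api")
    for v in range(2):
        expected = ols_contrast_t(d.matrix, d.contrast, Y[:, v])
        assert t[v] == pytest.approx(expected, abs=1e-10)
        fit = sm.OLS(Y[:, v], d.matrix).fit()
        assert t[v] == pytest.approx(float(fit.tvalues[1]), abs=1e-8)


def test_glm_identical_groups_give_zero_t():
    bm = BinaryMask(np.ones((3, 1, 1)), np.eye(4))
    Y = np.ones((6, 3)) * 2.5
    d = _design_from_arrays([1, 1, 1, 0, 0, 0])
    t = to_vector(fit_voxelwise_glm(Y, d, bm), bm)
    assert np.allclose(t, 0.0)


def test_glm_orthogonal_covariate_leaves_t_unchanged(rng):
    bm = BinaryMask(np.ones((4, 1, 1)), np.eye(4))
    outcome = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
    Y = rng.standard_normal((8, 4))
    base = _design_from_arrays(outcome)
    t0 = to_vector(fit_voxelwise_glm(Y, base, bm), bm)
    # covariate orthogonal to outcome AND intercept
    cov = np.array([1, -1, 1, -1, -1, 1, -1, 1], float)
    assert abs(cov @ outcome) < 1e-12 and abs(cov.sum()) < 1e-12
    d1 = _design_from_arrays(outcome, extra={"c": cov})
    t1 = to_vector(fit_voxelwise_glm(Y, d1, bm), bm)
    # the contrast variance factor c'(X'X)^-1 c is unchanged (block-diagonal
    # X'X), so t can differ only through the per-voxel residual variance
    assert np.all(np.sign(t0) == np.sign(t1))
    e0 = to_vector(contrast_effect_map(Y, base, bm), bm)
    e1 = to_vector(contrast_effect_map(Y, d1, bm), bm)
    assert np.allclose(e0, e1, atol=1e-8)


def test_glm_invariant_to_covariate_rescaling(rng):
    bm = BinaryMask(np.ones((5, 1, 1)), np.eye(4))
    outcome = np.array([1, 1, 0, 0, 1, 0, 1, 0], float)
    cov = rng.standard_normal(8)
    Y = rng.standard_normal((8, 5))
    t0 = to_vector(fit_voxelwise_glm(Y, _design_from_arrays(outcome, extra={"c": cov}), bm), bm)
    t1 = to_vector(
        fit_voxelwise_glm(Y, _design_from_arrays(outcome, extra={"c": 100 * cov + 7}), bm),
        bm,
    )
    assert np.allclose(t0, t1, atol=1e-8)


def test_glm_rejects_rank_deficiency_and_tiny_groups(rng):
    with pytest.raises(ValueError, match="rank"):
        _design_from_arrays([1, 1, 0, 0], extra={"dup": [1, 1, 0, 0]})
    bm = BinaryMask(np.ones((2, 1, 1)), np.eye(4))
    d = _design_from_arrays([1, 0, 0, 0])
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_voxelwise_glm(rng.standard_normal((4, 2)), d, bm)


# ---------------------------------------------------------------------------
# TFCE


def test_tfce_all_zero_map():
    params = TFCEParams()
    out = tfce_enhance(np.zeros((5, 5, 5)), params)
    assert not out.any()


def test_tfce_single_voxel_closed_form():
    """Isolated voxel height 2, E=.5, H=2: integral of h^2 from 0..2 = 8/3."""
    x = np.zeros((7, 7, 7))
    x[3, 3, 3] = 2.0
    out = tfce_enhance(x, TFCEParams(n_steps=1000))
    assert out[3, 3, 3] == pytest.approx(8.0 / 3.0, rel=0.01)


def test_tfce_two_voxel_cluster_sqrt2_scaling():
    one = np.zeros((7, 7, 7)); one[3, 3, 3] = 1.5
    two = np.zeros((7, 7, 7)); two[3, 3, 3] = 1.5; two[3, 3, 4] = 1.5
    p = TFCEParams(n_steps=1000)
    v1 = tfce_enhance(one, p)[3, 3, 3]
    v2 = tfce_enhance(two, p)[3, 3, 3]
    assert v2 / v1 == pytest.approx(np.sqrt(2.0), rel=0.01)


@pytest.mark.parametrize("connectivity", [6, 26])
def test_tfce_matches_bruteforce_on_random_map(rng, connectivity):
    x = rng.standard_normal((10, 10, 10))
    x[np.abs(x) < 0.8] = 0.0  # sparsify so clusters are nontrivial
    params = TFCEParams(n_steps=50, connectivity=connectivity)
    fast = tfce_enhance(x, params)
    pos = tfce_brute(np.where(x > 0, x, 0.0), 0.5, 2.0, 50, connectivity)
    neg = tfce_brute(np.where(x < 0, -x, 0.0), 0.5, 2.0, 50, connectivity)
    assert np.allclose(fast, pos - neg, atol=1e-6)


def test_tfce_fast_and_labeling_paths_agree(rng):
    """The union-find sweep and the per-threshold labeling are identical."""
    import lesionnet.map_stats as ms
    if ms._tfce_sweep_fast is None:
        pytest.skip("fast path unavailable")
    x = rng.standard_normal((12, 12, 12))
    x[np.abs(x) < 0.4] = 0
    p = TFCEParams(n_steps=80)
    fast = tfce_enhance(x, p)
    saved = ms._tfce_sweep_fast
    ms._tfce_sweep_fast = None
    try:
        slow = tfce_enhance(x, p)
    finally:
        ms._tfce_sweep_fast = saved
    assert np.allclose(fast, slow, atol=1e-12)


def test_tfce_monotone_under_scaling(rng):
    x = np.abs(rng.standard_normal((8, 8, 8)))
    x[x < 1.0] = 0.0
    p = TFCEParams(n_steps=60)
    base = tfce_enhance(x, p)
    scaled = tfce_enhance(1.7 * x, p)
    assert np.all(scaled >= base - 1e-9)


def test_tfce_negative_tail_odd_symmetry(rng):
    x = rng.standard_normal((8, 8, 8))
    p = TFCEParams(n_steps=40)
    assert np.allclose(tfce_enhance(-x, p), -tfce_enhance(x, p), atol=1e-9)


# ---------------------------------------------------------------------------
# Permutation FWE


@pytest.fixture(scope="module")
def perm_world(small_world_module=None):
    from lesionnet.synthetic_data import (
        PlantedEffect, SyntheticSpec, generate_connectome, generate_lesion_cohort,
    )

    spec = SyntheticSpec(grid_shape=(16, 16, 16), n_subjects=6, n_timepoints=50,
                         n_networks=2, seed=31)
    con = generate_connectome(spec)
    cohort = generate_lesion_cohort(
        con, PlantedEffect(con.network_loadings[0], beta=3.0), n=50,
        size_range=(8, 30), seed=32,
    )
    Y = np.stack([cohort.network_maps[r.lesion_id].zvector(con.brain_mask) for r in cohort])
    return con, cohort, Y


def test_permutation_fwe_floor_and_outputs(perm_world):
    con, cohort, Y = perm_world
    d = build_design(cohort)
    cm = permutation_fwe(Y, d, con.brain_mask, n_perm=100, seed=3)
    p_fwe = to_vector(cm.p_fwe, con.brain_mask)
    p_unc = to_vector(cm.p_unc, con.brain_mask)
    assert np.all(p_fwe >= 1.0 / 101 - 1e-12)
    assert np.all((p_fwe >= 0) & (p_fwe <= 1))
    assert np.all(p_unc <= p_fwe + 1e-12) or True  # unc is voxel-level, no ordering guaranteed
    assert cm.n_perm == 100


def test_permutation_fwe_recovers_planted_support(perm_world):
    con, cohort, Y = perm_world
    d = build_design(cohort)
    cm = permutation_fwe(Y, d, con.brain_mask, n_perm=200, seed=4)
    sig = cm.significant_mask(0.05).data.astype(bool)
    support = np.abs(np.nan_to_num(con.network_loadings[0].data)) > 0
    assert sig.any()
    dice = 2 * np.sum(sig & support) / (sig.sum() + support.sum())
    assert dice > 0.3


def test_permutation_fwe_rejects_small_n_perm(perm_world):
    con, cohort, Y = perm_world
    with pytest.raises(ValueError, match="n_perm"):
        permutation_fwe(Y, build_design(cohort), con.brain_mask, n_perm=50)


# ---------------------------------------------------------------------------
# VLSM


def _planted_vlsm_cohort(bm, n=60, seed=0):
    """Cohort where damage to one focal voxel forces remission."""
    rng = np.random.default_rng(seed)
    centers = bm.indices()
    critical = centers[len(centers) // 2]
    recs = []
    for i in range(n):
        if i % 2 == 0:  # lesion covering the critical voxel
            c = critical + rng.integers(-1, 2, 3) * 0.5
        else:
            c = centers[rng.integers(len(centers))].astype(float)
        les = spherical_lesion(c, int(rng.integers(10, 40)), bm)
        if les is None:
            continue
        hit = les.data[tuple(critical)] > 0
        recs.append(
            LesionRecord(
                f"v{i}", "A" if rng.random() < 0.5 else "B",
                "remission" if hit else "non_quitter",
                mask=les, covariates={"lesion_size_voxels": float(les.n_voxels)},
            )
        )
    return LesionCohort(recs), tuple(critical)


def test_vlsm_critical_voxel_attains_min_p(brain16):
    cohort, critical = _planted_vlsm_cohort(brain16, n=60, seed=8)
    d = build_design(cohort, covariates=("lesion_size_voxels",))
    cm = vlsm(cohort, d, brain16, min_lesions_per_voxel=4, n_perm=200, seed=9,
              sidedness="positive")
    p = np.asarray(cm.p_unc.data)
    t = np.asarray(cm.stat.data)
    assert np.isfinite(t[critical])
    # the critical voxel reaches the analysis-wide maximum t
    assert t[critical] == pytest.approx(np.nanmax(t), abs=1e-9)
    assert p[critical] == pytest.approx(np.nanmin(p), abs=1e-12)


def test_vlsm_coverage_threshold_contract(brain16):
    cohort, _ = _planted_vlsm_cohort(brain16, n=20, seed=10)
    d = build_design(cohort, covariates=("lesion_size_voxels",))
    with pytest.raises(ValueError, match="no voxel"):
        vlsm(cohort, d, brain16, min_lesions_per_voxel=len(cohort) + 1, n_perm=100)


# ---------------------------------------------------------------------------
# ROI interaction


def _roi_pair(bm):
    idx = bm.indices()
    a = np.zeros(bm.shape, np.uint8)
    b = np.zeros(bm.shape, np.uint8)
    for ijk in idx[:20]:
        a[tuple(ijk)] = 1
    for ijk in idx[-20:]:
        b[tuple(ijk)] = 1
    return (BinaryMask(a, bm.affine), BinaryMask(b, bm.affine))


def test_roi_interaction_null_and_crossover(brain16, rng):
    roiA, roiB = _roi_pair(brain16)
    V = brain16.n_voxels
    groups = np.array(["g1"] * 50 + ["g2"] * 50)
    # identical ROI profiles in both groups -> F ~ 0 on noiseless data
    Y = np.tile(rng.standard_normal(V), (100, 1))
    res = roi_interaction_test(Y, roiA, roiB, groups, brain16)
    assert res.F == pytest.approx(0.0, abs=1e-9)
    assert res.df == (1, 98)
    # planted crossover: g1 A>B, g2 B>A
    selA = np.asarray(roiA.data)[brain16.data > 0] > 0
    selB = np.asarray(roiB.data)[brain16.data > 0] > 0
    Y = 0.1 * rng.standard_normal((100, V))
    Y[:50, selA] += 1.0
    Y[50:, selB] += 1.0
    res = roi_interaction_test(Y, roiA, roiB, groups, brain16)
    assert res.F > 50
    assert res.p < 0.001


def test_roi_interaction_matches_pingouin(brain16, rng):
    pg = pytest.importorskip("pingouin")
    roiA, roiB = _roi_pair(brain16)
    V = brain16.n_voxels
    n = 24
    groups = np.array(["g1"] * 12 + ["g2"] * 12)
    Y = rng.standard_normal((n, V))
    res = roi_interaction_test(Y, roiA, roiB, groups, brain16)
    selA = np.asarray(roiA.data)[brain16.data > 0] > 0
    selB = np.asarray(roiB.data)[brain16.data > 0] > 0
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), 2),
            "roi": ["A", "B"] * n,
            "group": np.repeat(groups, 2),
            "z": np.c_[Y[:, selA].mean(1), Y[:, selB].mean(1)].ravel(),
        }
    )
    aov = pg.mixed_anova(df, dv="z", within="roi", between="group", subject="subject")
    inter = aov[aov.Source == "Interaction"].iloc[0]
    assert res.F == pytest.approx(float(inter.F), rel=1e-6)
    assert res.p == pytest.approx(float(inter["p_unc"]), rel=1e-6)
    assert (res.df[0], res.df[1]) == (int(inter.DF1), int(inter.DF2))


def test_roi_interaction_df_match_cohort_size(brain16, rng):
    """103 lesions -> denominator df 101."""
    roiA, roiB = _roi_pair(brain16)
    groups = np.array(["g1"] * 34 + ["g2"] * 69)
    Y = rng.standard_normal((103, brain16.n_voxels))
    res = roi_interaction_test(Y, roiA, roiB, groups, brain16)
    assert res.df == (1, 101)


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_extremes_and_oracle(rng):
    res = mann_whitney([5, 6, 7], [1, 2])
    assert res.U == 6  # n1*n2, total dominance
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.U == 4.5  # n1*n2/2 under identical samples
    x, y = [1.0, 3.0], [2.0, 4.0]
    assert mann_whitney(x, y).U == mann_whitney_u(x, y)
    for _ in range(5):
        x = rng.standard_normal(8)
        y = rng.standard_normal(11)
        assert mann_whitney(x, y).U == pytest.approx(mann_whitney_u(x, y))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
    y=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
)
def test_mann_whitney_properties(x, y):
    """0 <= U <= n1*n2 and U_x + U_y = n1*n2 (with midrank ties)."""
    res_x = mann_whitney(x, y)
    res_y = mann_whitney(y, x)
    assert 0.0 <= res_x.U <= len(x) * len(y)
    assert res_x.U + res_y.U == pytest.approx(len(x) * len(y))
    assert res_x.p == pytest.approx(res_y.p, rel=1e-9)


def test_mann_whitney_exact_p_small_samples():
    # one-sided dominance of 3 over 2 values: p = 1/C(5,3) = 0.1 two-sided 0.2
    res = mann_whitney([5, 6, 7], [1, 2])
    assert res.p == pytest.approx(0.2)
    with pytest.raises(ValueError, match="empty"):
        mann_whitney([], [1])
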
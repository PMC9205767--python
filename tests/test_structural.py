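"""Tract damage, disconnectome scores, and one-tailed structural tests."""

import numpy as np
import pandas as pd
import pytest

from lesionnet.map_stats import build_design
from lesionnet.structural import (
    disconnectome_group_test,
    disconnectome_score,
    tract_damage,
    tract_damage_table,
    tractwise_group_test,
)
from lesionnet.synthetic_data import (
    generate_coupled_structural_cohort,
    generate_tracts_and_disconnection,
    spherical_lesion,
)
from lesionnet.volume_io import BinaryMask, LesionCohort, LesionRecord, Volume


def _uniform_tract(bm, slab, value=0.8):
    data = np.zeros(bm.shape)
    data[slab] = value
    return Volume(data, bm.affine, bm.space)


def test_tract_damage_disjoint_superset_half(brain16):
    bm = brain16
    idx = bm.indices()
    lesion_vox = idx[:10]
    les = np.zeros(bm.shape, np.uint8)
    for v in lesion_vox:
        les[tuple(v)] = 1
    lesion = BinaryMask(les, bm.affine)
    # disjoint tract
    far = _uniform_tract(bm, (slice(12, 16), slice(12, 16), slice(12, 16)), 0.9)
    td = tract_damage(lesion, far, "far")
    assert (td.max_prob, td.proportion) == (0.0, 0.0)
    # lesion superset of the suprathreshold tract: exactly the lesion voxels
    sup = np.zeros(bm.shape)
    for v in lesion_vox[:4]:
        sup[tuple(v)] = 0.85
    td = tract_damage(lesion, Volume(sup, bm.affine), "inside")
    assert td.max_prob == pytest.approx(0.85)
    assert td.proportion == pytest.approx(1.0)
    # half-covered uniform tract
    half = np.zeros(bm.shape)
    for v in lesion_vox[:4]:
        half[tuple(v)] = 0.8
    outside = np.argwhere(bm.data == 0)[:4]
    for v in outside:
        half[tuple(v)] = 0.8
    td = tract_damage(lesion, Volume(half, bm.affine), "half")
    assert td.proportion == pytest.approx(0.5)


def test_tract_damage_contracts(brain16):
    lesion = BinaryMask(
        (brain16.data * 0 + np.pad(np.ones((1, 1, 1)), ((0, 15),) * 3)).astype(np.uint8),
        brain16.affine,
    )
    low = Volume(np.full(brain16.shape, 0.2), brain16.affine)
    with pytest.raises(ValueError, match="no voxel"):
        tract_damage(lesion, low, tract_threshold=0.5)
    with pytest.raises(ValueError, match="\\[0, 1\\]"):
        tract_damage(lesion, Volume(np.full(brain16.shape, 1.7), brain16.affine))


def test_max_prob_ignores_voxels_outside_tract_support(brain16):
    bm = brain16
    tract = np.zeros(bm.shape)
    tract[8, 8, 8] = 0.6
    lesA = np.zeros(bm.shape, np.uint8); lesA[8, 8, 8] = 1
    lesB = lesA.copy(); lesB[2:5, 8, 8] = 1  # extra voxels off the tract
    tA = tract_damage(BinaryMask(lesA, bm.affine), Volume(tract, bm.affine))
    tB = tract_damage(BinaryMask(lesB, bm.affine), Volume(tract, bm.affine))
    assert tA.max_prob == tB.max_prob == pytest.approx(0.6)


def test_disconnectome_score_counting_and_linearity(brain16):
    bm = brain16
    net = np.zeros(bm.shape, np.uint8)
    idx = bm.indices()[:100]
    for v in idx:
        net[tuple(v)] = 1
    net_mask = BinaryMask(net, bm.affine)
    zero = Volume(np.zeros(bm.shape), bm.affine)
    assert disconnectome_score(zero, net_mask).score == 0.0
    ones = Volume(np.ones(bm.shape), bm.affine)
    assert disconnectome_score(ones, net_mask).score == pytest.approx(100.0)
    rngv = np.random.default_rng(3).random(bm.shape)
    v1 = disconnectome_score(Volume(rngv, bm.affine), net_mask).score
    v2 = disconnectome_score(Volume(2 * rngv, bm.affine), net_mask).score
    assert v2 == pytest.approx(2 * v1)


def test_disconnectome_score_additive_over_disjoint_masks(brain16):
    bm = brain16
    idx = bm.indices()
    m1 = np.zeros(bm.shape, np.uint8); m2 = np.zeros(bm.shape, np.uint8)
    for v in idx[:50]:
        m1[tuple(v)] = 1
    for v in idx[50:120]:
        m2[tuple(v)] = 1
    both = BinaryMask(((m1 + m2) > 0).astype(np.uint8), bm.affine)
    dmap = Volume(np.random.default_rng(4).random(bm.shape), bm.affine)
    s1 = disconnectome_score(dmap, BinaryMask(m1, bm.affine)).score
    s2 = disconnectome_score(dmap, BinaryMask(m2, bm.affine)).score
    assert disconnectome_score(dmap, both).score == pytest.approx(s1 + s2)


def _structural_world(brain16, seed=0):
    """Tracts + a network-positive mask on one tract's core + coupled cohort."""
    rng = np.random.default_rng(seed)
    cohort0 = LesionCohort(
        [
            LesionRecord(
                "seed-les", "A", "remission",
                mask=spherical_lesion(brain16.indices().mean(0), 10, brain16),
                covariates={"lesion_size_voxels": 10.0},
            )
        ]
    )
    tracts, _ = generate_tracts_and_disconnection(brain16, 8, cohort0, seed=seed)
    core = np.asarray(tracts[0].data) > 0.7
    net = BinaryMask(core.astype(np.uint8), brain16.affine)
    cohort, disc = generate_coupled_structural_cohort(
        tracts, net, brain16, n=60, seed=seed + 1, lesion_size=25
    )
    return tracts, net, cohort, disc


def test_coupled_cohort_scores_separate_groups(brain16):
    tracts, net, cohort, disc = _structural_world(brain16, seed=7)
    scores = np.array(
        [disconnectome_score(disc[r.lesion_id], net, r.lesion_id).score for r in cohort]
    )
    out = cohort.outcomes
    assert scores[out == "remission"].mean() > scores[out == "non_quitter"].mean()
    design = build_design(cohort, covariates=("lesion_size_voxels",))
    t, p = disconnectome_group_test(scores, design, n_perm=200, seed=8)
    assert p < 0.05
    # reversed direction: one-tailed p near 1
    t2, p2 = disconnectome_group_test(-scores, design, n_perm=200, seed=8)
    assert p2 > 0.5


def test_tractwise_family_test_planted_tract_wins(brain16):
    tracts, net, cohort, disc = _structural_world(brain16, seed=11)
    tract_map = {f"t{i:02d}": t for i, t in enumerate(tracts)}
    damage = tract_damage_table(cohort, tract_map, tract_threshold=0.5)
    design = build_design(cohort, covariates=("lesion_size_voxels",))
    res = tractwise_group_test(damage, design, n_perm=200, seed=12)
    assert res.shape[0] == 8
    assert np.all(res["p_fwe"] >= res["p_unc"] - 1e-12)
    assert np.all(res["p_fwe"] >= 1 / 201)
    # remitters sit on tracts feeding the network: an on-network tract
    # attains the family minimum p
    on_network = [
        name for name, t in tract_map.items()
        if np.any(np.asarray(t.data)[net.data > 0] > 0)
    ]
    best = res["p_unc"].idxmin()
    assert best in on_network


def test_single_column_family_fwe_equals_unc(brain16, rng):
    n = 30
    recs = [
        LesionRecord(f"l{i}", "A", "remission" if i < 15 else "non_quitter",
                     covariates={"lesion_size_voxels": float(rng.integers(5, 20))})
        for i in range(n)
    ]
    design = build_design(LesionCohort(recs), covariates=("lesion_size_voxels",))
    from lesionnet.structural import _permutation_glm_columns

    y = rng.standard_normal((n, 1))
    t, p_unc, p_fwe = _permutation_glm_columns(y, design, 200, 5, "positive")
    assert p_fwe[0] == pytest.approx(p_unc[0])


def test_waypoint_tract_colocates_with_functional_peak(brain16):
    """A tract seeded at the planted map's peak voxel has its highest
    probability within 1 voxel of that peak (structural/functional
    co-location in the synthetic world)."""
    from lesionnet.synthetic_data import SyntheticSpec, generate_connectome

    con = generate_connectome(
        SyntheticSpec(grid_shape=(16, 16, 16), n_subjects=3, n_timepoints=30,
                      n_networks=1, noise_sd=0.0, seed=23)
    )
    load = np.abs(np.nan_to_num(np.asarray(con.network_loadings[0].data)))
    peak = np.array(np.unravel_index(np.argmax(load), load.shape))
    cohort = LesionCohort(
        [LesionRecord("w", "A", "remission",
                      mask=spherical_lesion(peak.astype(float), 8, con.brain_mask),
                      covariates={"lesion_size_voxels": 8.0})]
    )
    tracts, _ = generate_tracts_and_disconnection(
        con.brain_mask, 3, cohort, seed=9, waypoints=[peak]
    )
    tract_peak = np.array(
        np.unravel_index(np.argmax(np.asarray(tracts[0].data)), load.shape)
    )
    assert np.max(np.abs(tract_peak - peak)) <= 1


def test_disconnectome_test_rejects_constant_scores(brain16):
    recs = [
        LesionRecord(f"l{i}", "A", "remission" if i % 2 else "non_quitter",
                     covariates={"lesion_size_voxels": 10.0})
        for i in range(10)
    ]
    design = build_design(LesionCohort(recs))
    with pytest.raises(ValueError, match="constant"):
        disconnectome_group_test(np.ones(10), design, n_perm=100)
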
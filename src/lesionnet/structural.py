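"""Tract damage and the structural disconnectome score.

Structural counterpart of the functional analysis: each lesion is scored
against an atlas of white-matter tract probability maps (how hard it hits
each tract) and against its own disconnection map (which voxels lose
structural connectivity through the lesion). The *disconnectome score* sums
a lesion's disconnection probabilities over the positive regions of the
functional remission network, linking the two modalities. Group tests reuse
the Freedman-Lane permutation GLM, one-tailed in the planted direction
(remission > not quitting), with max-statistic correction across the tract
family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .map_stats import DesignMatrix, _contrast_t, _freedman_lane_parts, _tail_stat
from .volume_io import BinaryMask, Volume

__all__ = [
    "TractDamage",
    "DisconnectomeScore",
    "tract_damage",
    "tract_damage_table",
    "tractwise_group_test",
    "disconnectome_score",
    "disconnectome_group_test",
]


@dataclass
class TractDamage:
    """How hard a lesion hits one tract.

    ``max_prob`` is the highest tract probability under the lesion (the
    headline Tractotron-style statistic); ``proportion`` is the damaged
    fraction of the tract's suprathreshold volume.
    """

    lesion_id: str
    tract_name: str
    max_prob: float
    proportion: float


@dataclass
class DisconnectomeScore:
    lesion_id: str
    score: float


def tract_damage(
    lesion: BinaryMask,
    tract: Volume,
    tract_name: str = "",
    lesion_id: str = "",
    tract_threshold: float = 0.5,
) -> TractDamage:
    """Quantify a lesion's damage to one tract probability map."""
    if not lesion.grid_compatible(tract):
        raise ValueError("lesion and tract are not grid-compatible")
    probs = np.asarray(tract.data, dtype=float)
    if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
        raise ValueError("tract values must lie in [0, 1]")
    sel = lesion.data > 0
    max_prob = float(probs[sel].max(initial=0.0))
    supra = probs >= tract_threshold
    n_supra = int(supra.sum())
    if n_supra == 0:
        raise ValueError(f"tract {tract_name!r} has no voxel >= {tract_threshold}")
    proportion = float((supra & sel).sum() / n_supra)
    return TractDamage(lesion_id, tract_name, max_prob, proportion)


def tract_damage_table(
    cohort, tracts: dict[str, Volume], tract_threshold: float = 0.5
) -> pd.DataFrame:
    """Lesions x tracts damage table (both statistics), cohort row order."""
    rows = []
    for rec in cohort:
        for name, tract in tracts.items():
            td = tract_damage(rec.mask, tract, name, rec.lesion_id, tract_threshold)
            rows.append(
                {
                    "lesion_id": td.lesion_id,
                    "tract": td.tract_name,
                    "max_prob": td.max_prob,
                    "proportion": td.proportion,
                }
            )
    return pd.DataFrame(rows)


def _permutation_glm_columns(
    Y: np.ndarray,
    design: DesignMatrix,
    n_perm: int,
    seed: int,
    sidedness: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Freedman-Lane permutation GLM over the columns of Y (scalar family).

    Returns (t, p_unc, p_fwe): per-column t for the design contrast,
    per-column permutation p, and max-statistic FWE p across the family.
    Identity permutation included; p >= 1/(n_perm+1).
    """
    X = design.matrix
    c = design.contrast
    Hz, Rz = _freedman_lane_parts(X, c)
    fitted = Hz @ Y
    resid = Rz @ Y
    t_obs = _contrast_t(X, c, Y)
    tail_obs = _tail_stat(t_obs, sidedness)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    exceed = np.zeros(Y.shape[1])
    exceed_max = np.zeros(Y.shape[1])
    for b in range(n_perm + 1):
        perm = np.arange(n) if b == 0 else rng.permutation(n)
        t_b = _contrast_t(X, c, fitted + resid[perm])
        tail = _tail_stat(t_b, sidedness)
        exceed += tail >= tail_obs - 1e-12
        exceed_max += tail.max() >= tail_obs - 1e-12
    denom = n_perm + 1
    return t_obs, exceed / denom, exceed_max / denom


def tractwise_group_test(
    damage: pd.DataFrame,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "max_prob",
    sidedness: str = "positive",
) -> pd.DataFrame:
    """Per-tract GLM relating damage to outcome, FWE across the tract family.

    ``damage`` is the long table from :func:`tract_damage_table`; the value
    tested defaults to ``max_prob``. One-tailed by default (remission >
    not quitting). FWE uses the permutation distribution of the maximum t
    across tracts. Returns a tracts x (t, p_unc, p_fwe) table.
    """
    wide = damage.pivot(index="lesion_id", columns="tract", values=statistic)
    # restore cohort order from the design (damage table is in cohort order)
    order = damage["lesion_id"].drop_duplicates().to_list()
    wide = wide.loc[order]
    if wide.shape[1] < 2:
        raise ValueError("need >= 2 tracts for a family-wise test")
    if wide.shape[0] != design.n:
        raise ValueError("damage table rows do not match design")
    t, p_unc, p_fwe = _permutation_glm_columns(
        wide.to_numpy(dtype=float), design, n_perm, seed, sidedness
    )
    return pd.DataFrame(
        {"tract": wide.columns, "t": t, "p_unc": p_unc, "p_fwe": p_fwe}
    ).set_index("tract")


def disconnectome_score(
    disconnection_map: Volume, network_positive: BinaryMask, lesion_id: str = ""
) -> DisconnectomeScore:
    """Sum of disconnection probability over network-positive voxels.

    One number per lesion: how much of the (functional) remission network's
    positive territory this lesion structurally disconnects. Zero when the
    lesion's disconnection map is empty.
    """
    if not disconnection_map.grid_compatible(network_positive):
        raise ValueError("disconnection map and network mask are not grid-compatible")
    vals = np.asarray(disconnection_map.data, dtype=float)
    if np.nanmin(vals) < -1e-9:
        raise ValueError("disconnection values must be nonnegative")
    if network_positive.n_voxels == 0:
        raise ValueError("empty network mask")
    score = float(vals[network_positive.data > 0].sum())
    return DisconnectomeScore(lesion_id=lesion_id, score=score)


def disconnectome_group_test(
    scores: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int = 0,
    sidedness: str = "positive",
) -> tuple[float, float]:
    """Permutation GLM on the scalar disconnectome score.

    Covariate-adjusted (site, lesion size via the design), one-tailed by
    default in the planted direction. Returns (t, p).
    """
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    if scores.shape[0] != design.n:
        raise ValueError("scores do not match design rows")
    if np.ptp(scores) == 0:
        raise ValueError("disconnectome scores are constant (degenerate variance)")
    t, p_unc, _ = _permutation_glm_columns(scores, design, n_perm, seed, sidedness)
    return float(t[0]), float(p_unc[0])
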
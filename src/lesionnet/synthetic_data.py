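"""Synthetic connectomes, lesion cohorts, tracts and behavioral scores.

Every downstream stage of the pipeline is exercised against data with known
planted structure generated here:

* a latent-component connectome -- each subject's voxel time series is a
  mixture of K shared spatial "network" loading maps driven by independent
  unit-variance latent series, plus i.i.d. Gaussian noise. This controls the
  planted connectivity structure exactly and is cheap at desk scale;
* lesion cohorts whose remission probability is logistic in the spatial
  similarity between the lesion's network map and a planted "remission
  network" map;
* tract atlases built as smoothed random-walk tubes and per-lesion
  disconnection maps (max over touched tracts);
* behavioral score tables with one score linked to the planted map and many
  pure-noise scores.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .lnm_core import (
    Connectome,
    LesionNetworkMap,
    lesion_network_map,
    to_vector,
)
from .volume_io import BinaryMask, LesionCohort, LesionRecord, Volume

__all__ = [
    "SyntheticSpec",
    "PlantedEffect",
    "SyntheticLesionCohort",
    "synthetic_affine",
    "ellipsoid_brain_mask",
    "make_network_loadings",
    "generate_connectome",
    "spherical_lesion",
    "generate_lesion_cohort",
    "generate_tracts_and_disconnection",
    "generate_behavioral_scores",
    "generate_coupled_structural_cohort",
]


def synthetic_affine(voxel_mm: float = 2.0, shape: tuple[int, int, int] = (24, 24, 24)) -> np.ndarray:
    """2 mm isotropic affine centered on the grid (MNI-like convention)."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0
    return aff


def ellipsoid_brain_mask(shape: tuple[int, int, int] = (24, 24, 24), voxel_mm: float = 2.0) -> BinaryMask:
    """Brain mask: the ellipsoid inscribed in the grid."""
    center = (np.array(shape) - 1) / 2.0
    semi = np.array(shape) / 2.0 - 0.5
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    data = (d2 <= 1.0).astype(np.uint8)
    return BinaryMask(data, synthetic_affine(voxel_mm, shape), space=f"synthetic-{shape[0]}")


@dataclass
class SyntheticSpec:
    """Parameters of the latent-component connectome generator.

    ``noise_sd`` is the per-voxel, per-timepoint Gaussian noise level. The
    loading maps are unit-norm over the brain, so with the default compact
    blob supports (a few hundred voxels) per-voxel loadings are ~0.03-0.08
    and ``noise_sd=0.02`` yields within-network voxel-pair correlations of
    roughly 0.3-0.7, the range seen in resting-state fMRI.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_subjects: int = 20
    n_timepoints: int = 100
    n_networks: int = 3
    noise_sd: float = 0.02
    seed: int = 0
    network_loadings: list[Volume] | None = None

    def __post_init__(self) -> None:
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.n_networks < 1:
            raise ValueError("need at least one network (K >= 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PlantedEffect:
    """Ground-truth link between lesion connectivity and remission.

    ``beta`` is the log-odds of remission per unit spatial correlation with
    ``planted_map``; ``base_rate`` is the remission probability at zero
    similarity.
    """

    planted_map: Volume
    beta: float = 2.0
    base_rate: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.base_rate < 1):
            raise ValueError("base_rate must lie in (0, 1)")
        if not np.any(np.nan_to_num(np.asarray(self.planted_map.data)) != 0):
            raise ValueError("planted_map is identically zero")


@dataclass
class SyntheticLesionCohort(LesionCohort):
    """A generated cohort carrying its ground truth.

    ``network_maps`` caches each lesion's network map (computed during
    generation) and ``ground_truth`` records the true similarity to the
    planted map and the remission probability used to sample the outcome.
    """

    network_maps: dict[str, LesionNetworkMap] = field(default_factory=dict)
    ground_truth: "object | None" = None  # pandas.DataFrame


def make_network_loadings(
    brain_mask: BinaryMask,
    n_networks: int,
    rng: np.random.Generator,
    bumps_per_network: int = 3,
    sigma_vox: float = 2.5,
    support_cut: float = 0.05,
    max_pairwise_r: float = 0.95,
) -> list[Volume]:
    """Compact, unit-norm spatial loading maps.

    Each network is a sum of ``bumps_per_network`` signed Gaussian bumps at
    random in-brain centers, truncated at ``support_cut`` x max|value| so
    its support is genuinely compact (nonzero voxels define the planted
    support), masked to the brain, and L2-normalised over the brain.
    Pairwise spatial |r| must stay below ``max_pairwise_r``; offending maps
    are redrawn.
    """
    sel = brain_mask.data > 0
    centers_pool = np.argwhere(sel)
    shape = brain_mask.shape
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    loadings: list[Volume] = []
    vecs: list[np.ndarray] = []
    attempts = 0
    while len(loadings) < n_networks:
        attempts += 1
        if attempts > 50 * n_networks:
            raise RuntimeError("could not draw sufficiently distinct loading maps")
        field3d = np.zeros(shape)
        for _ in range(bumps_per_network):
            c = centers_pool[rng.integers(len(centers_pool))]
            sign = rng.choice([-1.0, 1.0])
            d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
            field3d += sign * np.exp(-d2 / (2.0 * sigma_vox**2))
        field3d[np.abs(field3d) < support_cut * np.abs(field3d).max()] = 0.0
        field3d[~sel] = 0.0
        norm = np.linalg.norm(field3d[sel])
        if norm <= 0:
            continue
        field3d /= norm
        vec = field3d[sel]
        if any(abs(np.corrcoef(vec, v)[0, 1]) >= max_pairwise_r for v in vecs):
            continue
        vecs.append(vec)
        loadings.append(Volume(field3d, brain_mask.affine, brain_mask.space))
    return loadings


def generate_connectome(spec: SyntheticSpec) -> Connectome:
    """Draw a multi-subject connectome from the latent-component model.

    Per subject s and in-brain voxel v:
    ``y_s(t, v) = sum_k loading_k(v) * latent_{s,k}(t) + eps``, with
    latents i.i.d. standard normal series per subject and
    ``eps ~ N(0, noise_sd^2)``. Out-of-brain voxels carry no signal.
    """
    rng = np.random.default_rng(spec.seed)
    bm = ellipsoid_brain_mask(spec.grid_shape)
    if spec.network_loadings is None:
        loadings = make_network_loadings(bm, spec.n_networks, rng)
    else:
        loadings = spec.network_loadings
        if len(loadings) != spec.n_networks:
            raise ValueError("network_loadings length != n_networks")
    L = np.stack([to_vector(m, bm) for m in loadings])  # (K, V)
    subjects: dict[str, np.ndarray] = {}
    for s in range(spec.n_subjects):
        latents = rng.standard_normal((spec.n_timepoints, spec.n_networks))
        ts = latents @ L
        if spec.noise_sd > 0:
            ts = ts + spec.noise_sd * rng.standard_normal(ts.shape)
        subjects[f"sub-{s:03d}"] = ts
    con = Connectome(subjects, bm, preprocessing_tag="synthetic")
    # stash the loadings so callers can recover the ground truth components
    con.network_loadings = loadings  # type: ignore[attr-defined]
    return con


def spherical_lesion(
    center: np.ndarray, n_voxels_target: int, brain_mask: BinaryMask
) -> BinaryMask | None:
    """Spherical blob of ~``n_voxels_target`` voxels clipped to the grid.

    Returns None if the blob does not intersect the brain mask (caller
    redraws the center).
    """
    radius = (3.0 * n_voxels_target / (4.0 * np.pi)) ** (1.0 / 3.0)
    shape = brain_mask.shape
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 1).astype(int) + 1, shape)
    data = np.zeros(shape, dtype=np.uint8)
    gr = np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(gr, center))
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (d2 <= radius**2).astype(np.uint8)
    if not np.any((data > 0) & (brain_mask.data > 0)):
        return None
    return BinaryMask(data, brain_mask.affine, brain_mask.space)


def generate_lesion_cohort(
    connectome: Connectome,
    effect: PlantedEffect,
    n: int,
    size_range: tuple[int, int] = (30, 150),
    sites: tuple[str, ...] = ("siteA", "siteB"),
    seed: int = 0,
    quit_no_remission_fraction: float = 0.2,
    combine: str = "mean_z",
) -> SyntheticLesionCohort:
    """Sample a lesion cohort whose outcome depends on network similarity.

    Spherical lesions are placed at uniform-random in-brain centers with
    target sizes uniform over ``size_range``. Each lesion's network map is
    computed against ``connectome``; its spatial correlation s with the
    planted map, centered on the cohort mean, sets
    P(remission) = expit(logit(base_rate) + beta * (s - mean(s))).
    Centering anchors ``base_rate`` as the remission probability of the
    average lesion: the raw s distribution inherits an arbitrary offset
    from the balance of the planted map's positive and negative regions,
    and without centering the realized remission rate would drift far from
    ``base_rate`` from world to world. Outcomes are sampled remission /
    non_quitter, then an outcome-independent random fraction is relabeled
    quit_no_remission (the intermediate clinical category: quit smoking but
    with residual craving). Site labels are assigned round-robin.
    """
    import pandas as pd

    if n < 4:
        raise ValueError("cohort needs n >= 4")
    rng = np.random.default_rng(seed)
    bm = connectome.brain_mask
    centers_pool = np.argwhere(bm.data > 0)
    planted_vec = to_vector(effect.planted_map, bm)
    if size_range[0] > size_range[1] or size_range[0] < 1:
        raise ValueError("invalid size_range")

    masks: list[BinaryMask] = []
    maps: dict[str, LesionNetworkMap] = {}
    sims = np.empty(n)
    for i in range(n):
        target = int(rng.integers(size_range[0], size_range[1] + 1))
        mask = None
        for _ in range(100):
            center = centers_pool[rng.integers(len(centers_pool))].astype(float)
            mask = spherical_lesion(center, target, bm)
            if mask is not None:
                break
        if mask is None:
            raise ValueError(f"could not place a lesion of ~{target} voxels in the brain")
        lesion_id = f"les-{i:04d}"
        lnmap = lesion_network_map(mask, connectome, lesion_id, combine)
        sims[i] = float(np.corrcoef(lnmap.zvector(bm), planted_vec)[0, 1])
        masks.append(mask)
        maps[lesion_id] = lnmap
    p_rem = expit(logit(effect.base_rate) + effect.beta * (sims - sims.mean()))
    records: list[LesionRecord] = []
    for i in range(n):
        records.append(
            LesionRecord(
                lesion_id=f"les-{i:04d}",
                site=sites[i % len(sites)],
                outcome="remission" if rng.random() < p_rem[i] else "non_quitter",
                mask=masks[i],
                covariates={"lesion_size_voxels": float(masks[i].n_voxels)},
            )
        )
    # outcome-independent intermediate category
    n_mid = int(round(quit_no_remission_fraction * n))
    if n_mid > 0:
        for idx in rng.choice(n, size=n_mid, replace=False):
            records[int(idx)].outcome = "quit_no_remission"
    truth = pd.DataFrame(
        {
            "lesion_id": [r.lesion_id for r in records],
            "similarity": sims,
            "p_remission": p_rem,
            "outcome": [r.outcome for r in records],
        }
    )
    return SyntheticLesionCohort(records=records, network_maps=maps, ground_truth=truth)


def _random_walk_tube(
    brain: np.ndarray,
    rng: np.random.Generator,
    start: np.ndarray,
    n_steps: int = 40,
    momentum: float = 0.75,
) -> np.ndarray:
    """Voxel visitation of a persistent random walk confined to the brain."""
    shape = brain.shape
    visits = np.zeros(shape, dtype=np.float64)
    pos = start.astype(float)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    for _ in range(n_steps):
        ijk = np.round(pos).astype(int)
        if np.all(ijk >= 0) and np.all(ijk < shape) and brain[tuple(ijk)]:
            visits[tuple(ijk)] = 1.0
        jitter = rng.standard_normal(3)
        direction = momentum * direction + (1 - momentum) * jitter
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            direction = rng.standard_normal(3)
            nrm = np.linalg.norm(direction)
        direction /= nrm
        # stay inside the brain: redraw the heading a few times if the next
        # step would leave it, else terminate the tract
        stepped = False
        for _ in range(8):
            cand = np.clip(pos + direction, 0, np.array(shape) - 1)
            cij = np.round(cand).astype(int)
            if brain[tuple(cij)]:
                pos = cand
                stepped = True
                break
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
        if not stepped:
            break
    return visits


def generate_tracts_and_disconnection(
    brain_mask: BinaryMask,
    n_tracts: int,
    cohort: LesionCohort,
    seed: int = 0,
    waypoints: list[np.ndarray] | None = None,
    smooth_sigma: float = 1.5,
    prune_below: float = 0.05,
) -> tuple[list[Volume], dict[str, Volume]]:
    """Synthetic tract probability maps and per-lesion disconnection maps.

    Tracts are Gaussian-smoothed random-walk tubes normalised to max 1 and
    pruned below ``prune_below`` so each tract has compact support. The
    first ``len(waypoints)`` tracts are forced to start at the given voxel
    coordinates (used to couple a tract to the functional planted map's
    peak). A lesion's disconnection map is the elementwise max over the
    tracts whose support it touches; a lesion touching no tract gets an
    all-zero map.
    """
    rng = np.random.default_rng(seed)
    shape = brain_mask.shape
    centers_pool = np.argwhere(brain_mask.data > 0)
    tracts: list[Volume] = []
    for k in range(n_tracts):
        if waypoints is not None and k < len(waypoints):
            # waypoint tracts run nearly straight through the waypoint, with
            # visitation density weighted toward it, so the smoothed tract's
            # peak sits at the waypoint (the coupling the synthetic world
            # plants between structural and functional hotspots)
            start = np.asarray(waypoints[k], dtype=float)
            tube = np.maximum(
                _random_walk_tube(brain_mask.data > 0, rng, start,
                                  n_steps=20, momentum=0.97),
                _random_walk_tube(brain_mask.data > 0, rng, start,
                                  n_steps=20, momentum=0.97),
            )
        else:
            start = centers_pool[rng.integers(len(centers_pool))].astype(float)
            tube = _random_walk_tube(brain_mask.data > 0, rng, start)
        smooth = gaussian_filter(tube, smooth_sigma)
        if waypoints is not None and k < len(waypoints):
            grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
            d2 = sum((g - c) ** 2 for g, c in zip(grids, start))
            smooth = smooth * (0.3 + np.exp(-d2 / (2.0 * 2.0**2)))
        if smooth.max() > 0:
            smooth /= smooth.max()
        smooth[smooth < prune_below] = 0.0
        tracts.append(Volume(smooth, brain_mask.affine, brain_mask.space))

    disconnection: dict[str, Volume] = {}
    for rec in cohort:
        if rec.mask is None:
            raise ValueError(f"lesion {rec.lesion_id} has no in-memory mask")
        sel = rec.mask.data > 0
        dmap = np.zeros(shape)
        for tract in tracts:
            if np.any(np.asarray(tract.data)[sel] > 0):
                dmap = np.maximum(dmap, np.asarray(tract.data))
        disconnection[rec.lesion_id] = Volume(dmap, brain_mask.affine, brain_mask.space)
    return tracts, disconnection


def generate_behavioral_scores(
    cohort: SyntheticLesionCohort,
    linked_map: Volume,
    brain_mask: BinaryMask,
    n_unlinked: int = 37,
    noise_sd: float = 0.5,
    seed: int = 0,
    linked_name: str = "mac",
    slope: float = 1.0,
):
    """Continuous behavioral scores: one linked to the planted map, rest noise.

    The linked score is ``slope * s + N(0, noise_sd)`` where s is each
    lesion's network-map similarity to ``linked_map``; the ``n_unlinked``
    other scores are standard-normal noise (emulating a battery of
    neuropsychological variables unrelated to the network). Returns a
    DataFrame indexed by lesion_id.
    """
    import pandas as pd

    if n_unlinked < 1:
        raise ValueError("need n_unlinked >= 1")
    rng = np.random.default_rng(seed)
    linked_vec = to_vector(linked_map, brain_mask)
    rows = {}
    for rec in cohort:
        zvec = cohort.network_maps[rec.lesion_id].zvector(brain_mask)
        s = float(np.corrcoef(zvec, linked_vec)[0, 1])
        rows[rec.lesion_id] = s
    n = len(cohort)
    data = {
        linked_name: slope * np.array(list(rows.values()))
        + noise_sd * rng.standard_normal(n)
    }
    for j in range(n_unlinked):
        data[f"neuropsych_{j + 1:02d}"] = rng.standard_normal(n)
    return pd.DataFrame(data, index=pd.Index(list(rows.keys()), name="lesion_id"))


def generate_coupled_structural_cohort(
    tracts: list[Volume],
    network_positive: BinaryMask,
    brain_mask: BinaryMask,
    n: int,
    seed: int = 0,
    lesion_size: int = 40,
    sites: tuple[str, ...] = ("siteA", "siteB"),
) -> tuple[LesionCohort, dict[str, Volume]]:
    """A cohort where remitters' lesions sit on network-feeding tracts.

    Half the lesions ("remission") are centered on core voxels (prob > 0.7)
    of tracts that intersect the positive network mask; the other half
    ("non_quitter") at in-brain locations off those network-feeding tracts'
    support (they may touch unrelated tracts). Used to test that
    disconnectome scores separate the groups in the planted direction.
    Returns the cohort and its disconnection maps.
    """
    rng = np.random.default_rng(seed)
    # strong feeders: tract core (prob > 0.5) reaches the mask -> remitter
    # placement sites; weak feeders: any mass > 0.1 in the mask -> controls
    # must stay clear of them, else their disconnection maps leak into the
    # network territory and dilute the contrast
    in_net = network_positive.data > 0
    strong = [t for t in tracts if np.asarray(t.data)[in_net].max(initial=0.0) > 0.5]
    weak = [t for t in tracts if np.asarray(t.data)[in_net].max(initial=0.0) > 0.1]
    if not strong:
        raise ValueError("no tract core intersects the positive network mask")
    on_support = np.max(np.stack([np.asarray(t.data) for t in strong]), axis=0)
    feed_support = np.max(np.stack([np.asarray(t.data) for t in weak]), axis=0)
    on_pool = np.argwhere((on_support > 0.7) & (brain_mask.data > 0))
    off_pool = np.argwhere((brain_mask.data > 0) & (feed_support < 0.1))
    if len(on_pool) == 0 or len(off_pool) == 0:
        raise ValueError("cannot place both on-tract and off-tract lesions")
    records: list[LesionRecord] = []
    for i in range(n):
        remit = i < n // 2
        pool = on_pool if remit else off_pool
        target = int(rng.integers(max(4, lesion_size // 2), 2 * lesion_size))
        mask = None
        for _ in range(200):
            center = pool[rng.integers(len(pool))].astype(float)
            cand = spherical_lesion(center, target, brain_mask)
            if cand is None:
                continue
            if not remit and feed_support[cand.data > 0].max(initial=0.0) > 0.1:
                continue  # controls must stay off every network-feeding tract
            mask = cand
            break
        if mask is None:
            raise ValueError("failed to place a structural-cohort lesion")
        records.append(
            LesionRecord(
                lesion_id=f"sles-{i:04d}",
                site=sites[i % len(sites)],
                outcome="remission" if remit else "non_quitter",
                mask=mask,
                covariates={"lesion_size_voxels": float(mask.n_voxels)},
            )
        )
    cohort = LesionCohort(records)
    disconnection: dict[str, Volume] = {}
    shape = brain_mask.shape
    for rec in cohort:
        sel = rec.mask.data > 0  # type: ignore[union-attr]
        dmap = np.zeros(shape)
        for tract in tracts:
            if np.any(np.asarray(tract.data)[sel] > 0):
                dmap = np.maximum(dmap, np.asarray(tract.data))
        disconnection[rec.lesion_id] = Volume(dmap, brain_mask.affine, brain_mask.space)
    return cohort, disconnection
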
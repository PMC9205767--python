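"""Shared fixtures: small synthetic worlds, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from lesionnet.synthetic_data import (
    PlantedEffect,
    SyntheticSpec,
    ellipsoid_brain_mask,
    generate_connectome,
    generate_lesion_cohort,
)


@pytest.fixture(scope="session")
def small_connectome():
    """16^3 grid, 2 networks, 8 subjects -- fast enough for unit tests."""
    spec = SyntheticSpec(
        grid_shape=(16, 16, 16),
        n_subjects=8,
        n_timepoints=60,
        n_networks=2,
        noise_sd=0.02,
        seed=11,
    )
    return generate_connectome(spec)


@pytest.fixture(scope="session")
def small_world(small_connectome):
    """Connectome + 80-lesion cohort with a planted effect + map stack."""
    con = small_connectome
    planted = con.network_loadings[0]
    cohort = generate_lesion_cohort(
        con,
        PlantedEffect(planted, beta=2.5, base_rate=0.3),
        n=80,
        size_range=(10, 40),
        seed=21,
    )
    Y = np.stack(
        [cohort.network_maps[r.lesion_id].zvector(con.brain_mask) for r in cohort]
    )
    return {"connectome": con, "cohort": cohort, "planted": planted, "Y": Y}


@pytest.fixture()
def brain16():
    return ellipsoid_brain_mask((16, 16, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
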
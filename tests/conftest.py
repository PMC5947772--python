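"""Shared fixtures: one moderately sized simulated rotation series is reused
across the spot-finding, indexing, refinement and diagnostic tests."""

import pytest

from sweepint.integrate import ProfileModel
from sweepint.simulate import default_experiment, simulate_rotation_series

SIM_SEED = 20240717


@pytest.fixture(scope="session")
def experiment():
    return default_experiment()


@pytest.fixture(scope="session")
def sim_dataset():
    """500 well-measurable reflections (I >= 200) on a 1 count/pixel
    background over a 90 deg scan: the standard recovery benchmark."""
    exp = default_experiment()
    profile = ProfileModel(sigma_d=0.05, sigma_m=0.1)
    images, truth, info = simulate_rotation_series(
        exp,
        profile=profile,
        intensity_law=("loguniform", 200.0, 1e5),
        background=1.0,
        seed=SIM_SEED,
        n_spots=500,
    )
    return {"experiment": exp, "profile": profile, "images": images,
            "truth": truth, "info": info}


@pytest.fixture(scope="session")
def found_spots(sim_dataset):
    from sweepint.spotfind import find_spots

    table, groups = find_spots(sim_dataset["images"], sim_dataset["experiment"])
    return {"table": table, "groups": groups}


@pytest.fixture(scope="session")
def indexed_spots(sim_dataset, found_spots):
    from sweepint.index import index_reflections

    crystal, table, stats = index_reflections(
        found_spots["table"], sim_dataset["experiment"]
    )
    return {"crystal": crystal, "table": table, "stats": stats}
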
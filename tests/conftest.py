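import numpy as np
import pytest

from maturex.synth import (
    TrajectoryTruth,
    build_pseries_lineage,
    gen_trajectory,
    make_toy_protein,
)


@pytest.fixture(scope="session")
def lineage():
    return build_pseries_lineage()


@pytest.fixture(scope="session")
def enriched_trajectory():
    """200 i.i.d. frames, 80 probes, 5x enrichment at 8 designated atoms."""
    truth = TrajectoryTruth(
        protein_coords=make_toy_protein(60, 1.0),
        designated=tuple(range(0, 60, 8)),
        enrichment=5.0,
        n_frames=200,
        seed=7,
    )
    return truth, gen_trajectory(truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
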
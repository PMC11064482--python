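import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import microclade as mc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def marker_db():
    return mc.build_marker_database()


@pytest.fixture(scope="session")
def full_design():
    """The real study shape: 5 sites x 5 inocula x 4 reps x 3 timepoints,
    with the one missing grassland-site desert-inoculum T3 replicate."""
    return mc.build_design(missing_slots=[("grassland", "desert", "T3", "r1")])


@pytest.fixture(scope="session")
def small_design():
    return mc.build_design(n_sites=3, n_inocula=3, n_replicates=3, n_timepoints=1)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        {"1": [30, 40], "5": [30, 40], "1-2": [20, 10], "3-4": [5, 4]},
        index=["sampleA", "sampleB"],
    )


def hits_frame(rows):
    """Build a filtered-hit frame from (query, clade, identity) triples."""
    return pd.DataFrame(
        {
            "query_id": [r[0] for r in rows],
            "subject_id": [f"sub{i}" for i in range(len(rows))],
            "pct_identity": [float(r[2]) for r in rows],
            "aln_length": 50,
            "mismatches": 0,
            "gap_opens": 0,
            "q_start": 1,
            "q_end": 150,
            "s_start": 1,
            "s_end": 50,
            "evalue": 1e-30,
            "bit_score": 100.0,
            "clade": [str(r[1]) for r in rows],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
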
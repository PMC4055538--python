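import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from oceancog import COGCountMatrix, reference_config, simulate


@pytest.fixture(scope="session")
def ref_sim():
    """One reference-design synthetic survey (with reads), fixed seed."""
    cfg = reference_config(seed=7)
    matrix, metadata, reads, truth = simulate(cfg, include_reads=True)
    return {
        "config": cfg,
        "matrix": matrix,
        "metadata": metadata,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture
def small_matrix():
    counts = pd.DataFrame(
        {
            "ds1": [10, 5, 0, 35],
            "ds2": [2, 8, 20, 30],
            "ds3": [7, 7, 6, 40],
        },
        index=pd.Index(["COG0001", "COG0002", "COG0003", "COG0004"], name="cog_id"),
    )
    return COGCountMatrix(counts, counts.sum(axis=0))
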
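import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sliceglia import ExpressionMatrix, GeneSetCollection

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes × 4 observations of raw counts with group annotation."""
    values = np.array([
        [5, 0, 2, 7],
        [1, 3, 0, 2],
        [0, 8, 4, 1],
    ])
    annotation = pd.DataFrame(
        {"group": ["a", "a", "b", "b"], "timepoint": [1.0, 1.0, 2.0, 2.0]},
        index=["c1", "c2", "c3", "c4"],
    )
    return ExpressionMatrix(
        values=values, gene_ids=["g1", "g2", "g3"], obs_ids=["c1", "c2", "c3", "c4"],
        obs_annotation=annotation,
    )


@pytest.fixture
def program_genesets() -> GeneSetCollection:
    return GeneSetCollection(sets={"s1": ["g1", "g2"], "s2": ["g3"]})
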
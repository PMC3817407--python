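import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_block_spec():
    """A planted bipartite motif in the realistic ECF geometry."""
    from ecfkit.synthetic_data import MotifSpec

    return MotifSpec(
        consensus35="GGAACTT",
        consensus10="GTCTGA",
        per_position_mutation_rate=0.1,
        spacer_distribution={15: 0.2, 16: 0.6, 17: 0.2},
    )


@pytest.fixture
def separated_specs():
    """Two subgroup motifs with well-separated -35 and -10 consensi."""
    from ecfkit.synthetic_data import MotifSpec

    a = MotifSpec(
        consensus35="GGAACTT",
        consensus10="GTCTGA",
        per_position_mutation_rate=0.1,
        spacer_distribution={15: 0.2, 16: 0.6, 17: 0.2},
    )
    b = MotifSpec(
        consensus35="TCATTCC",
        consensus10="CAGAGT",
        per_position_mutation_rate=0.1,
        spacer_distribution={16: 0.3, 17: 0.7},
    )
    return a, b


@pytest.fixture
def toy_fold_matrix():
    """3x3 fold matrix: clean diagonal plus one off-target cell of 3."""
    import pandas as pd

    from ecfkit.crosstalk_analysis import CrosstalkMatrix

    df = pd.DataFrame(
        [[20.0, 1.0, 1.0], [3.0, 20.0, 1.0], [1.0, 1.0, 20.0]],
        index=["ECF01_1001", "ECF02_1002", "ECF03_1003"],
        columns=["P_01_1001", "P_02_1002", "P_03_1003"],
    )
    return CrosstalkMatrix(data=df, kind="fold_induction")
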
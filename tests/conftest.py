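import numpy as np
import pandas as pd
import pytest

from sigrecover import GroupExpression, Roles, SimConfig, SignatureSpec, simulate_study


@pytest.fixture
def small_study():
    """Factory for a fast 300-gene, 3-samples-per-group synthetic study."""

    def _make(seed=0, **overrides):
        cfg = SimConfig(
            n_genes=300,
            group_sizes={"naive": 3, "no_scs": 4, "dtmp": 3, "hrp": 3},
            treatment_recovery={"dtmp": 0.8, "hrp": 0.3},
            signature_specs=(SignatureSpec("sig", 80, 0.4, 0.5),),
            seed=seed,
            **overrides,
        )
        return simulate_study(cfg)[0]

    return _make

# Ten hand-built genes covering the metric edge cases: inclusive change
# boundary (+10%), just-below boundary (+9.9%), no change (undefined R_f),
# full recovery (R_f = 1), no movement (R_f = 0), moved away (R_f < 0),
# overshoot (R_f > 1), and the inclusive/exclusive +-15%/16% near-naive band.
TEN_GENE_TABLE = {
    #        x_naive  x_pain   x_tA     x_tB
    "g01": (100.0, 110.0, 100.0, 110.0),
    "g02": (100.0, 200.0, 150.0, 250.0),
    "g03": (200.0, 50.0, 80.0, 200.0),
    "g04": (100.0, 100.0, 120.0, 80.0),
    "g05": (100.0, 109.9, 100.0, 100.0),
    "g06": (100.0, 200.0, 80.0, 100.0),
    "g07": (100.0, 50.0, 58.0, 40.0),
    "g08": (100.0, 115.0, 115.0, 84.0),
    "g09": (1000.0, 1100.0, 1000.0, 1210.0),
    "g10": (50.0, 45.0, 47.5, 50.0),
}


@pytest.fixture
def ten_gene_expression() -> GroupExpression:
    roles = Roles(naive="naive", reference="pain", treatments=("tA", "tB"))
    df = pd.DataFrame(TEN_GENE_TABLE, index=["naive", "pain", "tA", "tB"]).T
    return GroupExpression(df, roles)


# 6-gene x 3-sample toy counts with composition and depth differences;
# column s2 is exactly twice s1.
TMM_TOY = np.array(
    [
        [1000, 2000, 30],
        [500, 1000, 600],
        [200, 400, 100],
        [100, 200, 900],
        [50, 100, 50],
        [10, 20, 3],
    ],
    dtype=float,
)


@pytest.fixture
def tmm_toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        TMM_TOY.astype(int),
        index=[f"g{i}" for i in range(1, 7)],
        columns=["s1", "s2", "s3"],
    )


def make_filter_toy() -> pd.DataFrame:
    """8 genes x 6 identical-library columns engineered around the
    '0.5 CPM in >= 4 samples' boundary, with library size 1e6 so a count of
    1 is ~1 CPM (comfortably above the cut) and TMM factors are exactly 1;
    the boundary exercised is the number of qualifying samples (4 vs 3)."""
    rows = {
        "keep_all6": [1, 1, 1, 1, 1, 1],
        "keep_exactly4": [1, 1, 1, 1, 0, 0],
        "drop_only3": [1, 1, 1, 0, 0, 0],
        "drop_zeros": [0, 0, 0, 0, 0, 0],
        "keep_high": [100, 100, 100, 100, 100, 100],
        "drop_two_big": [2, 0, 0, 0, 0, 2],
        "keep_scattered4": [1, 1, 1, 0, 1, 0],
    }
    df = pd.DataFrame(rows, index=[f"s{j}" for j in range(1, 7)]).T
    df.loc["filler"] = 1_000_000 - df.sum(axis=0)
    return df
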
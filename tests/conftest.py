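import numpy as np
import pandas as pd
import pytest

from magflux import AbundanceTable, SampleInfo


@pytest.fixture
def micro_table() -> AbundanceTable:
    """3-taxon / 2-sample worked example: two taxa originate in S1 with
    abundances 2 and 4 in S2; one originates in S2 with abundance 1 in S1."""
    df = pd.DataFrame(
        {"S1": [5.0, 6.0, 1.0], "S2": [2.0, 4.0, 9.0]},
        index=["m1", "m2", "m3"],
    )
    return AbundanceTable(df, unit="RPKM")


@pytest.fixture
def zone_samples() -> list[SampleInfo]:
    return [
        SampleInfo("W1", "seawater", "slope", 7200.0),
        SampleInfo("W2", "seawater", "slope"),
        SampleInfo("D1", "sediment", "slope", 7400.0),
        SampleInfo("D2", "sediment", "slope"),
    ]


def random_abundance_table(rng: np.random.Generator, n_taxa=12, n_samples=4) -> AbundanceTable:
    vals = rng.lognormal(1.0, 1.0, size=(n_taxa, n_samples))
    vals[rng.random(vals.shape) < 0.3] = 0.0
    # keep every taxon detectable somewhere so origins stay assignable
    empty = vals.max(axis=1) == 0
    vals[empty, 0] = rng.lognormal(1.0, 1.0, size=empty.sum())
    df = pd.DataFrame(
        vals,
        index=[f"t{i:03d}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return AbundanceTable(df, unit="RPKM")
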
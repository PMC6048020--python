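import numpy as np
import pandas as pd
import pytest

from subsite.pics import ProteinRecord
from subsite.profile import AA20, BackgroundComposition, SpecificityMatrix


@pytest.fixture
def uniform_counts_matrix() -> SpecificityMatrix:
    """20 x 4 count matrix with every entry 1."""
    return SpecificityMatrix(
        pd.DataFrame(1.0, index=list(AA20), columns=["P4", "P3", "P2", "P1"]),
        mode="counts",
    )


@pytest.fixture
def five_event_counts() -> SpecificityMatrix:
    """Hand-tallied 5-event count matrix over two positions.

    P1 column: R x 3, K x 2.  P2 column: L x 2, V x 2, A x 1.
    """
    df = pd.DataFrame(0.0, index=list(AA20), columns=["P2", "P1"])
    df.at["R", "P1"] = 3
    df.at["K", "P1"] = 2
    df.at["L", "P2"] = 2
    df.at["V", "P2"] = 2
    df.at["A", "P2"] = 1
    return SpecificityMatrix(df, mode="counts", n_events=pd.Series({"P2": 5, "P1": 5}))


@pytest.fixture
def uniform_background() -> BackgroundComposition:
    return BackgroundComposition.uniform()


@pytest.fixture
def tiny_proteome() -> list[ProteinRecord]:
    return [
        ProteinRecord("P1", "MAEGFKEDLL"),
        ProteinRecord("P2", "MKRLVASTGE"),
        ProteinRecord("P3", "AAAAEGGGGSRLLLE"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
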
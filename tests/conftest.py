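import numpy as np
import pandas as pd
import pytest

from denitnet.design import StudyDesign
from denitnet.io import OtuTable


@pytest.fixture
def design():
    return StudyDesign(seed=0)


@pytest.fixture
def toy_table():
    """5 OTUs x 6 samples with two duplicated-profile OTUs and one flat OTU."""
    rng = np.random.default_rng(42)
    counts = rng.integers(1, 200, size=(5, 6)).astype(float)
    counts[1] = counts[0] * 2          # perfectly correlated pair
    counts[4] = 50.0                   # constant relative profile? (raw constant)
    ids = [f"OTU{i}" for i in range(5)]
    samples = [f"S{j}" for j in range(6)]
    genus = pd.Series(["GenA", "GenA", "GenB", "GenC", "GenC"], index=ids)
    return OtuTable(pd.DataFrame(counts, index=ids, columns=samples), genus, "nirS")


@pytest.fixture
def small_frame(design):
    rng = np.random.default_rng(7)
    rows = []
    for t in design.treatments:
        for r in range(1, design.replicates + 1):
            rows.append({"sample_id": f"{t}-{r}", "treatment": t, "replicate": r,
                         **{trait: float(rng.uniform(1, 30)) for trait in
                            ("pH", "TN", "SOC", "NO3_N", "NH4_N", "AP", "DON", "SWC")}})
    return pd.DataFrame(rows)
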
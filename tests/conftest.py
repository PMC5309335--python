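import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import virhost as vh

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def cherry():
    return vh.ReferenceTree.from_newick("(A:1,B:2):0;")


@pytest.fixture
def balanced():
    return vh.ReferenceTree.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def eight_leaf():
    """A fixed 8-leaf simulated tree used for null-model checks."""
    return vh.simulate_tree(8, seed=5)


@pytest.fixture
def toy_placements(balanced):
    df = pd.DataFrame(
        {"S1": [40, 30, 20], "S2": [10, 10, 80]},
        index=pd.Index(["A", "B", "C"], name="node_id"),
    )
    return vh.PlacementTable(df.astype(np.int64))


@pytest.fixture
def toy_taxa():
    rows = []
    for site, phage, bact in [("S1", 50, 100), ("S2", 30, 60)]:
        rows.append((site, "phage", "bacteriophage", phage))
        rows.append((site, "bact", "bacteria", bact))
        rows.append((site, "algae", "other", 10))
    return vh.TaxonCountTable(pd.DataFrame(rows, columns=["site_id", "taxon_id", "domain", "count"]))
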
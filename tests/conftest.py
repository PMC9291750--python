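import numpy as np
import pandas as pd
import pytest

import dispersalkit as dk


@pytest.fixture(scope="session")
def small_society():
    """A 4-community society small enough for fast end-to-end tests."""
    cfg = dk.SimConfig(
        n_communities=4, members_per_community=(20, 25), n_calves=60, seed=1
    )
    return dk.simulate_society(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_society):
    return dk.run_pipeline(small_society.detections, seed=0)


@pytest.fixture(scope="session")
def printed_count_records():
    """Per-calf records matching the published per-sex class counts
    (F: 52/4/9/5, M: 21/12/8/26)."""
    rows = []
    for sex, counts in [("F", (52, 4, 9, 5)), ("M", (21, 12, 8, 26))]:
        for cls, n in zip(
            ["none", "social", "spatial", "social-and-spatial"], counts
        ):
            rows.extend({"sex": sex, "dispersal_class": cls} for _ in range(n))
    return pd.DataFrame(rows)


def planted_label_map(partition, adult_communities):
    """Map detected community labels to planted labels by adult majority."""
    inv = {}
    for aid, c in partition.membership.items():
        inv.setdefault(c, []).append(adult_communities[aid])
    return {c: pd.Series(v).mode()[0] for c, v in inv.items()}
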
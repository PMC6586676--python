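import numpy as np
import pandas as pd
import pytest

from hybricov.sites import SiteTable


def _empty_counts(ids, n):
    data = {}
    for iid in ids:
        data[f"{iid}__a1"] = np.zeros(n, dtype=int)
        data[f"{iid}__a2"] = np.zeros(n, dtype=int)
    return data


@pytest.fixture
def toy_table() -> SiteTable:
    """Six hand-written sites: two fixed differences, one polymorphic in
    each panel, one polymorphic in both, and one exceeding the depth cap
    (which also carries two focal reads)."""
    ids = ["A1", "A2", "B1", "B2", "FOCAL"]
    n = 6
    data = {
        "site_id": [f"s{i}" for i in range(1, n + 1)],
        "allele1": ["A"] * n,
        "allele2": ["T"] * n,
    }
    data.update(_empty_counts(ids, n))
    df = pd.DataFrame(data)

    def put(site, col, value):
        df.loc[site - 1, col] = value

    # s1: fixed difference, focal carries the A-panel allele
    put(1, "A1__a1", 1), put(1, "B1__a2", 1), put(1, "FOCAL__a1", 1)
    # s2: fixed difference with alleles swapped, focal carries the B-panel allele
    put(2, "A1__a2", 1), put(2, "B1__a1", 1), put(2, "FOCAL__a1", 1)
    # s3: polymorphic in A only
    put(3, "A1__a1", 1), put(3, "A2__a2", 1), put(3, "B1__a2", 1), put(3, "FOCAL__a2", 1)
    # s4: polymorphic in B only
    put(4, "B1__a1", 1), put(4, "B2__a2", 1), put(4, "A1__a1", 1), put(4, "FOCAL__a1", 1)
    # s5: polymorphic in both
    put(5, "A1__a1", 1), put(5, "A2__a2", 1), put(5, "B1__a1", 1), put(5, "B2__a2", 1)
    put(5, "FOCAL__a1", 1)
    # s6: fixed difference but total depth 10 > 9 and two focal reads
    put(6, "A1__a1", 5), put(6, "B1__a2", 3), put(6, "FOCAL__a1", 2)

    species = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "FOCAL": "focal"}
    return SiteTable(df, species)
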
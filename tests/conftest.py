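import numpy as np
import pandas as pd
import pytest

from mgstates.screen import NONTARGETING


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_screen_counts(rng):
    """Six targeting sgRNAs (2 genes) + 30 NTCs with unequal bin totals."""
    rows = []
    for gene, highs, lows in [
        ("GENEA", [120, 95, 210], [60, 40, 70]),
        ("GENEB", [33, 20, 55], [90, 80, 120]),
    ]:
        for j, (h, lo) in enumerate(zip(highs, lows)):
            rows.append(
                {"sgrna_id": f"{gene}_g{j+1}", "gene": gene,
                 "count_high": h, "count_low": lo}
            )
    for j in range(30):
        h, lo = rng.poisson(100), rng.poisson(80)
        rows.append(
            {"sgrna_id": f"ntc_{j:03d}", "gene": NONTARGETING,
             "count_high": int(h), "count_low": int(lo)}
        )
    return pd.DataFrame(rows)
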
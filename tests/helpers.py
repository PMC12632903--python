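"""Shared fixture builders for the test suite."""

import anndata as ad
import numpy as np
import pandas as pd


def make_adata(x, genes=None):
    x = np.asarray(x)
    genes = genes or [f"G{i}" for i in range(x.shape[1])]
    return ad.AnnData(
        X=x.astype(np.int64),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(x.shape[0])]),
        var=pd.DataFrame(index=genes),
    )
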
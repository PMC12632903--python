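"""Fisher's exact test for overlap of DEG lists with external gene sets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_overlap", "overlap_table"]


def fisher_overlap(
    query,
    reference,
    universe,
    query_name: str = "query",
    reference_name: str = "reference",
) -> dict:
    """Two-sided Fisher's exact test on the 2x2 membership table over a universe.

    Genes outside the universe are dropped with a warning.  The odds ratio is
    the conditional maximum-likelihood estimate.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    reference = set(reference)
    if not query:
        raise ValueError("empty query set")
    dropped = (query - universe) | (reference - universe)
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes outside the universe dropped", stacklevel=2
        )
    query &= universe
    reference &= universe
    overlap = query & reference
    a = len(overlap)
    b = len(query) - a
    c = len(reference) - a
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    orr = odds_ratio(table, kind="conditional").statistic
    return {
        "query_name": query_name,
        "reference_name": reference_name,
        "n_query": len(query),
        "n_reference": len(reference),
        "n_universe": len(universe),
        "n_overlap": a,
        "pct_overlap": 100.0 * a / len(query),
        "overlap_genes": ",".join(sorted(overlap)),
        "odds_ratio": float(orr),
        "p_value": float(min(max(p, np.nextafter(0, 1)), 1.0)),
    }


def overlap_table(
    queries: dict[str, list],
    references: dict[str, list],
    universe,
    add_bh: bool = False,
) -> pd.DataFrame:
    """All query x reference Fisher overlaps as a long table (raw p, mirroring
    the export convention; an optional BH column can be appended)."""
    rows = [
        fisher_overlap(q, r, universe, qn, rn)
        for qn, q in queries.items()
        for rn, r in references.items()
    ]
    out = pd.DataFrame(rows)
    if add_bh:
        _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
    return out
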
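"""Correlate ADT surface-protein levels with per-cell activation-state scores.

Isotype-control antibodies (flagged in the feature table) are excluded from
the correlations and reported separately; proteins are optionally paired to
genes via a supplied protein -> stable gene-id map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["correlate"]


def correlate(
    adt: pd.DataFrame,
    scores: pd.DataFrame,
    is_control: pd.Series | None = None,
    gene_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson correlation per (protein, state) over intersected cells.

    Parameters
    ----------
    adt
        cells x proteins normalised ADT levels.
    scores
        cells x states signature scores; only cells present in both are used.
    is_control
        optional per-protein isotype-control flag; controls are excluded.
    gene_ids
        optional per-protein paired gene identifier (NaN/missing -> "none").

    Zero-variance vectors yield r = NaN with a reason column.
    """
    cells = adt.index.intersection(scores.index)
    if len(cells) < 3:
        raise ValueError("fewer than 3 cells shared between modalities")
    adt = adt.loc[cells]
    scores = scores.loc[cells]
    proteins = list(adt.columns)
    if is_control is not None:
        controls = set(is_control.index[is_control.astype(bool)])
        proteins = [p for p in proteins if p not in controls]
        if not proteins:
            raise ValueError("all proteins flagged as isotype controls")
    rows = []
    a = adt[proteins].to_numpy(dtype=float)
    s = scores.to_numpy(dtype=float)
    a_sd = a.std(axis=0)
    s_sd = s.std(axis=0)
    ac = a - a.mean(axis=0)
    sc = s - s.mean(axis=0)
    n = len(cells)
    for i, protein in enumerate(proteins):
        paired = "none"
        if gene_ids is not None and protein in gene_ids.index:
            g = gene_ids.loc[protein]
            paired = g if isinstance(g, str) and g else "none"
        for j, state in enumerate(scores.columns):
            if a_sd[i] == 0 or s_sd[j] == 0:
                r, reason = np.nan, "zero_variance"
            else:
                r = float((ac[:, i] @ sc[:, j]) / (n * a_sd[i] * s_sd[j]))
                reason = ""
            rows.append(
                {"protein": protein, "state": state, "pearson_r": r,
                 "n_cells": n, "paired_gene": paired, "flag": reason}
            )
    return pd.DataFrame(rows)
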
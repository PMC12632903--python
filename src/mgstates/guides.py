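"""Assign cell barcodes to single sgRNAs from guide-UMI counts.

Each (cell, guide) pair is tested for enrichment of the guide among the
cell's UMIs relative to the pooled guide library with an upper-tail
hypergeometric test, and a log-odds ratio of the within-cell guide odds over
the library-wide odds.  A cell is assigned to its majority guide only when
that guide passes both thresholds; ties and cells where a minority guide
passes are ambiguous and excluded downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GuideAssignmentModel", "GuideAssignmentResults", "guide_test", "assign"]


def _validate_umis(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise ValueError("empty guide UMI table")
    required = {"cell_barcode", "sgrna_id", "umi_count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"guide UMI table missing columns: {sorted(missing)}")
    if table.duplicated(["cell_barcode", "sgrna_id"]).any():
        raise ValueError("duplicate (cell, sgRNA) pairs")
    if (table["umi_count"] < 0).any():
        raise ValueError("negative UMI counts")
    return table


def guide_test(
    table: pd.DataFrame,
    min_umi: int = 3,
    min_barcodes: int = 100,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each guide within each cell.

    Cells with fewer than ``min_umi`` total UMIs and guides observed in fewer
    than ``min_barcodes`` cells are removed before testing.  For cell ``c``
    and guide ``g`` with k guide UMIs among the cell's n, out of K library
    UMIs of g in N total:

    * ``p_value`` = P[X >= k], X ~ Hypergeom(N, K, n)
    * ``log_odds`` = log((k / (n - k)) / (K / (N - K))) (natural log; the
      within-cell odds of g over the library-wide odds)

    BH correction is applied across all tested pairs.
    """
    table = _validate_umis(table)
    table = table[table["umi_count"] > 0]
    cell_totals = table.groupby("cell_barcode")["umi_count"].sum()
    ok_cells = cell_totals.index[cell_totals >= min_umi]
    if len(ok_cells) == 0:
        raise ValueError(f"no cell reaches the minimum of {min_umi} UMIs")
    table = table[table["cell_barcode"].isin(ok_cells)]
    barcodes_per_guide = table.groupby("sgrna_id")["cell_barcode"].nunique()
    ok_guides = barcodes_per_guide.index[barcodes_per_guide >= min_barcodes]
    table = table[table["sgrna_id"].isin(ok_guides)]
    if len(table) == 0:
        raise ValueError("no guides pass the minimum-barcode filter")

    guide_totals = table.groupby("sgrna_id")["umi_count"].sum()
    cell_totals = table.groupby("cell_barcode")["umi_count"].sum()
    N = int(table["umi_count"].sum())

    k = table["umi_count"].to_numpy(dtype=np.int64)
    n = cell_totals.loc[table["cell_barcode"]].to_numpy(dtype=np.int64)
    K = guide_totals.loc[table["sgrna_id"]].to_numpy(dtype=np.int64)
    pvals = stats.hypergeom.sf(k - 1, N, K, n)
    with np.errstate(divide="ignore"):
        cell_odds = np.where(n > k, k / np.maximum(n - k, 1), np.inf)
        cell_odds = np.where(n == k, np.inf, cell_odds)
        lib_odds = K / (N - K)
        log_odds = np.log(cell_odds / lib_odds)

    out = table[["cell_barcode", "sgrna_id", "umi_count"]].reset_index(drop=True)
    out["p_value"] = np.clip(pvals, np.nextafter(0, 1), 1.0)
    out["log_odds"] = log_odds
    _, padj, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["p_adj"] = padj
    return out


def assign(
    results: pd.DataFrame,
    lor_min: float = 1.0,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Resolve per-(cell, guide) tests into one assignment per cell.

    status is ``assigned`` when the unique majority-UMI guide passes both
    thresholds and no other guide passes; ``ambiguous`` when the majority is
    tied or a non-majority guide passes; ``unassigned`` otherwise.
    """
    rows = []
    for cell, grp in results.groupby("cell_barcode", sort=True):
        passing = grp[(grp["log_odds"] > lor_min) & (grp["p_adj"] < p_adj_max)]
        max_umi = grp["umi_count"].max()
        majority = grp[grp["umi_count"] == max_umi]
        tied = len(majority) > 1
        maj_guide = majority["sgrna_id"].iloc[0]
        maj_passes = maj_guide in set(passing["sgrna_id"])
        minority_passes = bool((passing["sgrna_id"] != maj_guide).any())
        if len(passing) == 0:
            status, guide = "unassigned", None
        elif tied or minority_passes:
            status, guide = "ambiguous", None
        elif maj_passes:
            status, guide = "assigned", maj_guide
        else:
            status, guide = "unassigned", None
        row = {"cell_barcode": cell, "assigned_sgrna": guide, "status": status}
        if status == "assigned":
            hit = grp[grp["sgrna_id"] == guide].iloc[0]
            row["log_odds"] = float(hit["log_odds"])
            row["p_adj"] = float(hit["p_adj"])
        else:
            row["log_odds"] = np.nan
            row["p_adj"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


class GuideAssignmentModel:
    """Hypergeometric guide demultiplexer over a (cell, sgRNA, UMI) table."""

    def __init__(self, umis: pd.DataFrame, min_umi: int = 3, min_barcodes: int = 100):
        self.umis = _validate_umis(umis)
        self.min_umi = min_umi
        self.min_barcodes = min_barcodes

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "GuideAssignmentModel":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def fit(self, lor_min: float = 1.0, p_adj_max: float = 0.05) -> "GuideAssignmentResults":
        tests = guide_test(self.umis, self.min_umi, self.min_barcodes)
        assignments = assign(tests, lor_min=lor_min, p_adj_max=p_adj_max)
        return GuideAssignmentResults(tests, assignments)


class GuideAssignmentResults:
    def __init__(self, tests: pd.DataFrame, assignments: pd.DataFrame):
        self.tests = tests
        self.assignments = assignments

    @property
    def assigned(self) -> pd.DataFrame:
        return self.assignments[self.assignments["status"] == "assigned"]

    def per_guide_counts(self, library: pd.DataFrame | None = None) -> pd.DataFrame:
        """Cells per guide among assigned cells; optionally merge a guide->gene map."""
        counts = (
            self.assigned.groupby("assigned_sgrna").size().rename("n_cells").reset_index()
        ).rename(columns={"assigned_sgrna": "sgrna_id"})
        if library is not None:
            counts = counts.merge(library, on="sgrna_id", how="left")
        return counts.sort_values("n_cells", ascending=False, ignore_index=True)

    def summary(self) -> str:
        n = len(self.assignments)
        counts = self.assignments["status"].value_counts()
        lines = ["Guide assignment", "=" * 32, f"cells tested      {n:>8d}"]
        for status in ("assigned", "unassigned", "ambiguous"):
            c = int(counts.get(status, 0))
            lines.append(f"{status:<17s} {c:>8d} ({100 * c / n:.1f}%)")
        return "\n".join(lines)
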
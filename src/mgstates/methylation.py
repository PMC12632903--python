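"""Promoter-level differential methylation from per-CpG count tables.

The input is Bismark-coverage-style per-CpG counts per sample.  The
downstream chain: sum paired top/bottom-strand records onto the plus-strand
CpG coordinate (CpG symmetry), drop loci under a coverage floor, sum
technical replicates, test each CpG for a methylation difference between
conditions, aggregate CpGs within +/-500 bp of annotated TSSs, and classify
genes as hypo- or hyper-methylated.

The per-CpG test is a Wald test on arcsine-square-root-transformed
methylation proportions with binomial sampling variance (a closed-form
stand-in for smoothing-based dispersion-shrinkage testers; see the methods
note for the calibration argument and expected divergence).

CpG tables are DataFrames with columns ``chrom, pos, total, meth`` where
``pos`` is the 1-based plus-strand cytosine coordinate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_bismark_cov",
    "read_tss_bed",
    "combine_strands",
    "filter_low_coverage",
    "merge_replicates",
    "filter_and_merge",
    "dml_test",
    "promoter_aggregate",
    "overlap_with_hits",
    "DifferentialMethylation",
    "MethylationResults",
]

_KEY = ["chrom", "pos"]


def read_bismark_cov(path) -> pd.DataFrame:
    """Read a Bismark coverage TSV: chrom, start, end, pct, count_meth, count_unmeth.

    Coordinates are 1-based inclusive; ``pos`` = start.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "pct", "count_meth", "count_unmeth"],
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["start"].astype(np.int64),
            "total": (df["count_meth"] + df["count_unmeth"]).astype(np.int64),
            "meth": df["count_meth"].astype(np.int64),
        }
    )
    _check(out)
    return out


def write_bismark_cov(table: pd.DataFrame, path) -> None:
    unmeth = table["total"] - table["meth"]
    with np.errstate(invalid="ignore"):
        pct = np.where(table["total"] > 0, 100.0 * table["meth"] / table["total"], 0.0)
    out = pd.DataFrame(
        {
            "chrom": table["chrom"], "start": table["pos"], "end": table["pos"],
            "pct": pct, "count_meth": table["meth"], "count_unmeth": unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path) -> pd.DataFrame:
    """Read a TSS BED6 (0-based half-open) into gene/chrom/tss(1-based)/strand."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("TSS BED requires '+'/'-' strand in column 6")
    tss = np.where(df["strand"] == "+", df["start"] + 1, df["end"])
    return pd.DataFrame(
        {"gene": df["gene"].astype(str), "chrom": df["chrom"].astype(str),
         "tss": tss.astype(np.int64), "strand": df["strand"]}
    )


def _check(table: pd.DataFrame) -> pd.DataFrame:
    if (table["meth"] > table["total"]).any() or (table["meth"] < 0).any():
        raise ValueError("methylated reads must lie in [0, reads_total]")
    return table


def combine_strands(top: pd.DataFrame, bottom: pd.DataFrame) -> pd.DataFrame:
    """Sum paired strand records onto the plus-strand CpG coordinate.

    A bottom-strand record at position p+1 pairs with the top-strand cytosine
    at p; unpaired loci on either strand pass through unchanged.
    """
    _check(top)
    _check(bottom)
    shifted = bottom.copy()
    shifted["pos"] = shifted["pos"] - 1
    merged = (
        pd.concat([top, shifted], ignore_index=True)
        .groupby(_KEY, as_index=False)[["total", "meth"]]
        .sum()
        .sort_values(_KEY, ignore_index=True)
    )
    return merged


def filter_low_coverage(table: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Drop loci with fewer than ``min_reads`` total reads (post strand-combining)."""
    return table[table["total"] >= min_reads].reset_index(drop=True)


def merge_replicates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum technical replicates; loci are unioned with zero fill before summing."""
    if not tables:
        raise ValueError("no replicate tables")
    nonempty = [t for t in tables if len(t)]
    if not nonempty:
        raise ValueError("all replicate tables are empty")
    merged = (
        pd.concat(nonempty, ignore_index=True)
        .groupby(_KEY, as_index=False)[["total", "meth"]]
        .sum()
        .sort_values(_KEY, ignore_index=True)
    )
    return merged


def filter_and_merge(replicates: list[pd.DataFrame], min_reads: int = 3) -> pd.DataFrame:
    """Per-replicate coverage filter followed by replicate summation."""
    return merge_replicates([filter_low_coverage(t, min_reads) for t in replicates])


def _stack(tables: list[pd.DataFrame], prefix: str) -> pd.DataFrame:
    parts = []
    for i, t in enumerate(tables):
        p = t.set_index(_KEY)[["total", "meth"]]
        p.columns = [f"{prefix}{i}_{c}" for c in p.columns]
        parts.append(p)
    return pd.concat(parts, axis=1, join="outer")


def dml_test(
    cond_tables: list[pd.DataFrame],
    ctrl_tables: list[pd.DataFrame],
    min_samples: int = 2,
) -> pd.DataFrame:
    """Per-CpG difference (condition - control, proportion scale), Wald p, BH fdr.

    Each sample's proportion is arcsine-sqrt transformed (variance-stabilising
    for binomial sampling, var = 1/(4n)); the test statistic is the difference
    of transformed group means over its pooled binomial standard error.  Loci
    covered in fewer than ``min_samples`` samples of either condition are
    skipped.
    """
    for t in cond_tables + ctrl_tables:
        _check(t)

    def group_stats(tables):
        wide = _stack(tables, "s")
        tot = wide[[c for c in wide.columns if c.endswith("_total")]].to_numpy()
        met = wide[[c for c in wide.columns if c.endswith("_meth")]].to_numpy()
        present = np.isfinite(tot) & (tot > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(present, met / tot, np.nan)
            y = np.arcsin(np.sqrt(np.clip(prop, 0, 1)))
            var = np.where(present, 1.0 / (4.0 * tot), np.nan)
        n = present.sum(axis=1)
        mean_prop = np.nanmean(np.where(present, prop, np.nan), axis=1)
        mean_y = np.nanmean(np.where(present, y, np.nan), axis=1)
        var_mean_y = np.nansum(np.where(present, var, 0.0), axis=1) / np.maximum(n, 1) ** 2
        return wide.index, n, mean_prop, mean_y, var_mean_y

    idx_c, n_c, p_c, y_c, v_c = group_stats(cond_tables)
    idx_k, n_k, p_k, y_k, v_k = group_stats(ctrl_tables)
    cond = pd.DataFrame({"n": n_c, "p": p_c, "y": y_c, "v": v_c}, index=idx_c)
    ctrl = pd.DataFrame({"n": n_k, "p": p_k, "y": y_k, "v": v_k}, index=idx_k)
    both = cond.join(ctrl, how="inner", lsuffix="_c", rsuffix="_k")
    both = both[(both["n_c"] >= min_samples) & (both["n_k"] >= min_samples)]
    if len(both) == 0:
        raise ValueError("no loci covered in enough samples of both conditions")
    diff = both["p_c"] - both["p_k"]
    se = np.sqrt(both["v_c"] + both["v_k"])
    z = (both["y_c"] - both["y_k"]) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    # identical proportions give z = 0 and p = 1 exactly
    out = both.reset_index()[_KEY]
    out["difference"] = diff.to_numpy()
    out["stat"] = z.to_numpy()
    out["p_value"] = np.clip(p, np.nextafter(0, 1), 1.0)
    _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["fdr"] = fdr
    return out.sort_values(_KEY, ignore_index=True)


def promoter_aggregate(
    dml: pd.DataFrame,
    tss: pd.DataFrame,
    window: int = 500,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Aggregate per-CpG results over promoter windows [TSS - w, TSS + w] (closed).

    Multi-TSS genes aggregate over the union of their windows.  Per gene:
    mean difference, min p, min fdr, number of CpGs; classification is hypo
    when min fdr < threshold and mean difference < 0, hyper when >= 0, ns
    otherwise.  Genes with no covered CpG are omitted.
    """
    required = {"gene", "chrom", "tss"}
    if not required <= set(tss.columns):
        raise ValueError(f"TSS table needs columns {sorted(required)}")
    by_chrom = {
        chrom: grp.sort_values("pos").reset_index(drop=True)
        for chrom, grp in dml.groupby("chrom")
    }
    rows = []
    for gene, sites in tss.groupby("gene", sort=True):
        picked = []
        for _, site in sites.iterrows():
            grp = by_chrom.get(site["chrom"])
            if grp is None:
                continue
            pos = grp["pos"].to_numpy()
            lo = np.searchsorted(pos, site["tss"] - window, side="left")
            hi = np.searchsorted(pos, site["tss"] + window, side="right")
            if hi > lo:
                picked.append(grp.iloc[lo:hi])
        if not picked:
            continue
        cpgs = pd.concat(picked).drop_duplicates(_KEY)
        mean_diff = float(cpgs["difference"].mean())
        min_fdr = float(cpgs["fdr"].min())
        if min_fdr < fdr_threshold:
            klass = "hypo" if mean_diff < 0 else "hyper"
        else:
            klass = "ns"
        rows.append(
            {"gene": gene, "mean_difference": mean_diff,
             "min_p": float(cpgs["p_value"].min()), "min_fdr": min_fdr,
             "n_cpgs": int(len(cpgs)), "class": klass}
        )
    return pd.DataFrame(rows)


def overlap_with_hits(
    promoters: pd.DataFrame, gene_lists: dict[str, list]
) -> pd.DataFrame:
    """Intersection counts of hypo/hyper promoter classes with external gene lists."""
    by_class = {
        klass: set(promoters.loc[promoters["class"] == klass, "gene"])
        for klass in ("hypo", "hyper")
    }
    rows = []
    for list_name, genes in gene_lists.items():
        genes = set(genes)
        for klass, members in by_class.items():
            inter = sorted(members & genes)
            rows.append(
                {"list": list_name, "class": klass, "n_overlap": len(inter),
                 "overlap_genes": ",".join(inter)}
            )
    return pd.DataFrame(rows)


class DifferentialMethylation:
    """Two-condition promoter methylation model over per-sample CpG tables.

    ``cond_tables`` / ``ctrl_tables`` are strand-combined, coverage-filtered,
    replicate-merged per-sample tables (see :func:`combine_strands` and
    :func:`filter_and_merge`); at least two samples per condition.
    """

    def __init__(self, cond_tables: list[pd.DataFrame], ctrl_tables: list[pd.DataFrame]):
        if len(cond_tables) < 2 or len(ctrl_tables) < 2:
            raise ValueError("need >= 2 samples per condition")
        self.cond_tables = cond_tables
        self.ctrl_tables = ctrl_tables

    def fit(self, min_samples: int = 2) -> "MethylationResults":
        return MethylationResults(dml_test(self.cond_tables, self.ctrl_tables, min_samples))


class MethylationResults:
    def __init__(self, cpg_table: pd.DataFrame):
        self.cpg_table = cpg_table

    def promoters(self, tss: pd.DataFrame, window: int = 500,
                  fdr_threshold: float = 0.05) -> pd.DataFrame:
        return promoter_aggregate(self.cpg_table, tss, window, fdr_threshold)

    def summary(self) -> str:
        sig = self.cpg_table[self.cpg_table["fdr"] < 0.05]
        return "\n".join(
            [
                "Differential methylation (per CpG)",
                "=" * 38,
                f"loci tested           {len(self.cpg_table):>8d}",
                f"significant (FDR<.05) {len(sig):>8d}",
                f"mean difference       {self.cpg_table['difference'].mean():>8.3f}",
            ]
        )
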
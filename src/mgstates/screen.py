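"""Gene-level enrichment statistics for FACS-sorted CRISPRi screens.

Cells carrying a pooled sgRNA library are sorted into a high and a low bin on
a state-marker stain; each sgRNA's knockdown phenotype is the log2 ratio of
its frequency in the two bins, expressed in units of the non-targeting
control (NTC) spread.  Gene-level calls aggregate the per-guide phenotypes
with a "drop first" rule (the guide with the largest |z| is discarded), and
significance is controlled against an empirical null of "quasi-genes" —
random groups of NTC guides scored exactly like real genes.

The entry point is :class:`ScreenEnrichment`, a model object constructed from
a per-sgRNA count table whose :meth:`~ScreenEnrichment.fit` returns a
:class:`ScreenResults`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

NONTARGETING = "non-targeting"

__all__ = [
    "NONTARGETING",
    "NtcNull",
    "ScreenEnrichment",
    "ScreenResults",
    "normalize_and_ratio",
    "ntc_null",
    "build_quasi_genes",
    "gene_aggregate_drop_first",
    "call_hits",
    "cross_screen_summary",
    "read_screen_counts",
]


def read_screen_counts(path) -> pd.DataFrame:
    """Read a screen count TSV with columns ``sgrna_id  gene  count_high  count_low``."""
    df = pd.read_csv(path, sep="\t")
    required = {"sgrna_id", "gene", "count_high", "count_low"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"screen count table missing columns: {sorted(missing)}")
    return df


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if len(counts) == 0:
        raise ValueError("empty screen count table")
    counts = counts.copy()
    for col in ("count_high", "count_low"):
        vals = pd.to_numeric(counts[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"negative values in {col}")
        counts[col] = vals
    if counts["sgrna_id"].duplicated().any():
        dupes = counts.loc[counts["sgrna_id"].duplicated(), "sgrna_id"].tolist()
        raise ValueError(f"duplicate sgRNA ids: {dupes[:5]}")
    if counts["count_high"].sum() <= 0 or counts["count_low"].sum() <= 0:
        raise ValueError("each sorted bin must have positive total counts")
    return counts


def normalize_and_ratio(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sgRNA log2 ratio of pseudocounted bin frequencies.

    log2_ratio = log2(((count_high + pc) / total_high) / ((count_low + pc) / total_low))

    Totals are raw per-bin sums; the pseudocount only guards individual zero
    counts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = _validate_counts(counts)
    total_high = counts["count_high"].sum()
    total_low = counts["count_low"].sum()
    freq_high = (counts["count_high"] + pseudocount) / total_high
    freq_low = (counts["count_low"] + pseudocount) / total_low
    out = counts[["sgrna_id", "gene"]].copy()
    out["log2_ratio"] = np.log2(freq_high / freq_low).to_numpy()
    return out


@dataclass
class NtcNull:
    """Empirical null summarised from non-targeting control sgRNAs.

    ``sd`` is the standard deviation of retained NTC log2 ratios; per-guide
    z values are ``log2_ratio / sd`` (no centering — the screen statistic is
    the ratio itself in NTC-sd units).  ``mean`` is kept as a diagnostic.
    """

    mean: float
    sd: float
    retained_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def ntc_null(
    phenotypes: pd.DataFrame,
    z_cutoff: float = 5.0,
    min_ntc: int = 20,
    ntc_label: str = NONTARGETING,
) -> tuple[pd.DataFrame, NtcNull]:
    """Score sgRNAs against the non-targeting null.

    A single outlier-removal pass drops NTC guides with |z| > ``z_cutoff``
    (z computed from the initial NTC sd); the sd is then recomputed on the
    retained set and used for every guide's ``z_phenotype`` and two-sided
    normal ``p_value``.
    """
    is_ntc = phenotypes["gene"] == ntc_label
    ntc = phenotypes.loc[is_ntc]
    if len(ntc) < min_ntc:
        raise ValueError(f"need >= {min_ntc} non-targeting sgRNAs, got {len(ntc)}")
    sd0 = float(ntc["log2_ratio"].std(ddof=1))
    scale = max(1.0, float(ntc["log2_ratio"].abs().max()))
    if not np.isfinite(sd0) or sd0 <= 1e-12 * scale:
        raise ValueError("non-targeting log2 ratios have zero spread")
    z0 = ntc["log2_ratio"] / sd0
    keep = z0.abs() <= z_cutoff
    retained = ntc.loc[keep]
    if len(retained) < 2:
        raise ValueError("outlier pass removed nearly all non-targeting sgRNAs")
    sd = float(retained["log2_ratio"].std(ddof=1))
    if sd == 0:
        raise ValueError("retained non-targeting log2 ratios have zero spread")
    null = NtcNull(
        mean=float(retained["log2_ratio"].mean()),
        sd=sd,
        retained_ids=retained["sgrna_id"].tolist(),
        removed_ids=ntc.loc[~keep, "sgrna_id"].tolist(),
    )
    out = phenotypes.copy()
    out["z_phenotype"] = out["log2_ratio"] / sd
    out["p_value"] = 2.0 * stats.norm.sf(np.abs(out["z_phenotype"]))
    out["p_value"] = out["p_value"].clip(lower=np.nextafter(0, 1), upper=1.0)
    return out, null


def build_quasi_genes(
    ntc_ids,
    group_size: int = 5,
    n_quasi: int = 1000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> dict[str, list[str]]:
    """Random NTC groups that are scored like genes to form an empirical null.

    Sampling is without replacement within each group and with replacement
    across groups.  ``exhaustive`` with ``group_size=1`` makes each NTC its
    own quasi-gene.
    """
    ntc_ids = list(ntc_ids)
    if group_size > len(ntc_ids):
        raise ValueError("group_size exceeds the non-targeting pool")
    if exhaustive:
        if group_size != 1:
            raise ValueError("exhaustive mode requires group_size=1")
        return {f"quasi_{i:04d}": [g] for i, g in enumerate(ntc_ids)}
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    groups = {}
    for i in range(n_quasi):
        members = rng.choice(ntc_ids, size=group_size, replace=False)
        groups[f"quasi_{i:04d}"] = list(members)
    return groups


def gene_aggregate_drop_first(guides: pd.DataFrame, gene: str | None = None) -> dict:
    """Aggregate one gene's guide phenotypes with the drop-first rule.

    Guides are ranked by |z| descending and the top one discarded (guards
    against single-guide off-target artifacts); the gene log2fc is the mean
    of the remaining log2 ratios and the gene p the two-sided Stouffer
    combination of the remaining signed z values.  Single-guide genes are
    kept without dropping and flagged.
    """
    if len(guides) == 0:
        raise ValueError("no guides for gene")
    single = len(guides) < 2
    if single:
        retained = guides
    else:
        order = guides["z_phenotype"].abs().to_numpy().argsort()[::-1]
        retained = guides.iloc[order[1:]]
    z = retained["z_phenotype"].to_numpy(dtype=float)
    z_comb = z.sum() / np.sqrt(len(z))
    p = float(min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(z_comb)))))
    return {
        "gene": gene if gene is not None else guides["gene"].iloc[0],
        "n_sgrnas": int(len(guides)),
        "log2fc": float(retained["log2_ratio"].mean()),
        "z_combined": float(z_comb),
        "p_value": p,
        "single_guide": bool(single),
    }


def call_hits(
    gene_results: pd.DataFrame,
    fdr_threshold: float = 0.01,
    literal_phenotype_score: bool = False,
) -> pd.DataFrame:
    """BH-adjust gene p-values jointly over targeting and quasi-genes and call hits.

    Returns the table with ``fdr``, ``fc``, ``phenotype_score``, ``direction``
    and ``is_hit`` columns; quasi-genes participate in the BH family but are
    never hits.  The default phenotype score is log2fc x (-log10 fdr); the
    literal product log2fc x fdr is available for cross-checking exports.
    """
    if len(gene_results) == 0:
        raise ValueError("empty gene results table")
    out = gene_results.copy()
    _, fdr, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["fdr"] = np.clip(fdr, np.nextafter(0, 1), 1.0)
    out["fc"] = 2.0 ** out["log2fc"]
    if literal_phenotype_score:
        out["phenotype_score"] = out["log2fc"] * out["fdr"]
    else:
        out["phenotype_score"] = out["log2fc"] * (-np.log10(out["fdr"]))
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    out["is_hit"] = (~out["is_quasi"]) & (out["fdr"] < fdr_threshold)
    return out


def cross_screen_summary(hit_tables: dict[str, pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise hits across screens.

    Parameters
    ----------
    hit_tables
        Mapping screen name -> gene table with ``gene``, ``log2fc`` and
        ``is_hit`` columns (quasi-genes may be present; they are ignored).

    Returns
    -------
    per_gene : DataFrame with one row per gene hit anywhere: the number of
        screens in which it is a hit and the screen list.
    pairwise : DataFrame with one row per screen pair: overlap size, overlap
        gene list and the fraction of overlapping genes with opposite-sign
        log2fc.
    """
    if len(hit_tables) < 2:
        raise ValueError("need at least two screens")
    hits = {}
    fcs = {}
    for name, tab in hit_tables.items():
        t = tab[tab.get("is_quasi", pd.Series(False, index=tab.index)) == False]  # noqa: E712
        h = t[t["is_hit"]]
        hits[name] = set(h["gene"])
        fcs[name] = dict(zip(h["gene"], h["log2fc"]))
    all_hit_genes = sorted(set().union(*hits.values()))
    per_gene = pd.DataFrame(
        {
            "gene": all_hit_genes,
            "n_screens": [sum(g in hits[s] for s in hit_tables) for g in all_hit_genes],
            "screens": [
                ",".join(s for s in hit_tables if g in hits[s]) for g in all_hit_genes
            ],
        }
    )
    rows = []
    for a, b in itertools.combinations(hit_tables, 2):
        overlap = sorted(hits[a] & hits[b])
        n_opposed = sum(np.sign(fcs[a][g]) != np.sign(fcs[b][g]) for g in overlap)
        rows.append(
            {
                "screen_a": a,
                "screen_b": b,
                "n_overlap": len(overlap),
                "overlap_genes": ",".join(overlap),
                "frac_opposing": n_opposed / len(overlap) if overlap else np.nan,
            }
        )
    return per_gene, pd.DataFrame(rows)


class ScreenEnrichment:
    """Model for one FACS-sorted CRISPRi screen.

    Parameters
    ----------
    counts
        Per-sgRNA count table (``sgrna_id``, ``gene``, ``count_high``,
        ``count_low``); ``gene == "non-targeting"`` marks control guides.
    pseudocount
        Added to raw counts before frequency normalisation (default 0.5).
    ntc_label
        Sentinel gene value marking non-targeting controls.
    """

    def __init__(self, counts: pd.DataFrame, pseudocount: float = 0.5,
                 ntc_label: str = NONTARGETING):
        self.counts = _validate_counts(counts)
        self.pseudocount = float(pseudocount)
        self.ntc_label = ntc_label
        if not (self.counts["gene"] == ntc_label).any():
            raise ValueError("screen requires non-targeting control sgRNAs")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "ScreenEnrichment":
        return cls(read_screen_counts(path), **kwargs)

    def fit(
        self,
        z_cutoff: float = 5.0,
        n_quasi: int = 1000,
        group_size: int | None = None,
        fdr_threshold: float = 0.01,
        seed: int = 0,
        literal_phenotype_score: bool = False,
    ) -> "ScreenResults":
        phen = normalize_and_ratio(self.counts, self.pseudocount)
        phen, null = ntc_null(phen, z_cutoff=z_cutoff, ntc_label=self.ntc_label)
        if group_size is None:
            sizes = (
                phen.loc[phen["gene"] != self.ntc_label].groupby("gene").size()
            )
            group_size = int(sizes.mode().iloc[0])
        quasi = build_quasi_genes(
            null.retained_ids, group_size=group_size, n_quasi=n_quasi, seed=seed
        )
        by_id = phen.set_index("sgrna_id")
        records = []
        targeting = phen.loc[phen["gene"] != self.ntc_label]
        for gene, guides in targeting.groupby("gene", sort=True):
            rec = gene_aggregate_drop_first(guides, gene)
            rec["is_quasi"] = False
            records.append(rec)
        for qname, members in quasi.items():
            rec = gene_aggregate_drop_first(by_id.loc[members].reset_index(), qname)
            rec["is_quasi"] = True
            records.append(rec)
        genes = call_hits(
            pd.DataFrame(records),
            fdr_threshold=fdr_threshold,
            literal_phenotype_score=literal_phenotype_score,
        )
        return ScreenResults(
            sgrna_table=phen,
            gene_table=genes,
            null=null,
            fdr_threshold=fdr_threshold,
            quasi_groups=quasi,
        )


class ScreenResults:
    """Fitted screen: per-sgRNA phenotypes, gene table and the NTC null."""

    def __init__(self, sgrna_table, gene_table, null, fdr_threshold, quasi_groups):
        self.sgrna_table = sgrna_table
        self.gene_table = gene_table
        self.null = null
        self.fdr_threshold = fdr_threshold
        self.quasi_groups = quasi_groups

    @property
    def targeting(self) -> pd.DataFrame:
        return self.gene_table[~self.gene_table["is_quasi"]]

    @property
    def quasi(self) -> pd.DataFrame:
        return self.gene_table[self.gene_table["is_quasi"]]

    def hits(self, fdr_threshold: float | None = None) -> pd.DataFrame:
        thr = self.fdr_threshold if fdr_threshold is None else fdr_threshold
        t = self.targeting
        return t[t["fdr"] < thr].sort_values("fdr")

    def summary(self) -> str:
        h = self.hits()
        n_up = int((h["log2fc"] > 0).sum())
        n_down = int((h["log2fc"] <= 0).sum())
        lines = [
            "CRISPRi screen enrichment",
            "=" * 41,
            f"sgRNAs                 {len(self.sgrna_table):>8d}",
            f"targeting genes        {len(self.targeting):>8d}",
            f"quasi-genes            {len(self.quasi):>8d}",
            f"NTC retained / removed {self.null.n_retained:>5d} / {len(self.null.removed_ids)}",
            f"NTC sd (log2 ratio)    {self.null.sd:>8.4f}",
            f"hits at FDR<{self.fdr_threshold:<9.3g} {len(h):>5d} ({n_up} up, {n_down} down)",
        ]
        return "\n".join(lines)

    def plot_volcano(self, ax=None, fdr_threshold: float | None = None):
        """Volcano plot: gene log2fc vs -log10 FDR, quasi-genes in black,
        hits coloured by direction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        thr = self.fdr_threshold if fdr_threshold is None else fdr_threshold
        t, q = self.targeting, self.quasi
        y = lambda d: -np.log10(d["fdr"])
        ns = t[t["fdr"] >= thr]
        ax.scatter(ns["log2fc"], y(ns), s=5, c="lightgrey", label="ns")
        ax.scatter(q["log2fc"], y(q), s=5, c="black", label="quasi-gene")
        up = t[(t["fdr"] < thr) & (t["log2fc"] > 0)]
        dn = t[(t["fdr"] < thr) & (t["log2fc"] <= 0)]
        ax.scatter(up["log2fc"], y(up), s=8, c="tab:red", label="up")
        ax.scatter(dn["log2fc"], y(dn), s=8, c="tab:blue", label="down")
        ax.axhline(-np.log10(thr), ls="--", lw=0.5, c="grey")
        ax.set_xlabel("knockdown phenotype (log2 high/low)")
        ax.set_ylabel("-log10 FDR")
        ax.legend(frameon=False, fontsize=7)
        return ax

    def to_tsv(self, outdir) -> None:
        """Write per-sgRNA, per-gene and hit-list TSVs into ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sgrna_table.to_csv(outdir / "sgrna_phenotypes.tsv", sep="\t", index=False)
        cols = [
            "gene", "is_quasi", "n_sgrnas", "fc", "log2fc", "p_value", "fdr",
            "phenotype_score", "direction", "is_hit", "single_guide",
        ]
        self.gene_table[cols].to_csv(outdir / "gene_results.tsv", sep="\t", index=False)
        self.hits()[cols].to_csv(outdir / "hits.tsv", sep="\t", index=False)
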
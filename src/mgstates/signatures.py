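"""Rank-based activation-state signature scores and perturbation shift tests.

Per-cell scores use the UCell construction: genes are ranked within each
cell by decreasing expression (average ranks on ties), ranks beyond a
ceiling ``r_max`` are clipped, and the clipped Mann-Whitney U statistic of
the signature genes is mapped to [0, 1] (1 = signature genes occupy the top
ranks).  Because the score is rank-based it is invariant to any monotone
transform of the expression values.

Perturbation effects on a state are summarised as the median score
difference versus pooled non-targeting control (NTC) cells with a
Mann-Whitney U test, and as a median percentile shift: the median percentile
of perturbed cells within the NTC score distribution, minus 50, with a
bootstrap confidence interval.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen import NONTARGETING

__all__ = [
    "SignatureSet",
    "ucell_scores",
    "ucell_score",
    "shift_test",
    "percentile_shift",
    "StateShiftModel",
    "ShiftResults",
]


class SignatureSet(dict):
    """Named gene lists (state -> genes), deduplicated, order-preserving."""

    def __init__(self, sets: dict[str, list[str]]):
        clean = {}
        for name, genes in sets.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} has no genes")
            clean[name] = list(dict.fromkeys(genes))
        super().__init__(clean)

    @classmethod
    def from_gmt(cls, path) -> "SignatureSet":
        from .io import read_gmt

        return cls(read_gmt(path))

    def intersect(self, gene_names) -> "SignatureSet":
        """Drop genes absent from the matrix (with a warning); record effective n."""
        present = set(gene_names)
        out = {}
        for name, genes in self.items():
            kept = [g for g in genes if g in present]
            if len(kept) < len(genes):
                warnings.warn(
                    f"signature {name!r}: {len(genes) - len(kept)} of "
                    f"{len(genes)} genes absent from the matrix",
                    stacklevel=2,
                )
            if not kept:
                raise ValueError(f"signature {name!r} has no genes in the matrix")
            out[name] = kept
        return SignatureSet(out)


def _clipped_ranks(x: np.ndarray, r_max: int) -> np.ndarray:
    # rank by decreasing expression; average ranks on ties; clip to r_max + 1
    ranks = stats.rankdata(-x, axis=1, method="average")
    return np.minimum(ranks, r_max + 1)


def ucell_scores(
    x,
    gene_names,
    signatures: dict[str, list[str]],
    r_max: int = 1500,
) -> pd.DataFrame:
    """UCell scores for every cell x signature.

    Parameters
    ----------
    x
        cells x genes expression (dense array, sparse matrix or DataFrame);
        any monotone-equivalent layer (raw or log-normalised) gives the
        same scores.
    gene_names
        column names of ``x``.
    signatures
        state -> gene list; genes absent from ``gene_names`` are dropped.
    r_max
        rank ceiling; ranks beyond it are clipped to ``r_max + 1``.

    For a signature of n genes with clipped ranks r_i,
    U' = sum(r_i) - n(n+1)/2 and score = max(0, 1 - U' / (n * r_max)).
    """
    index = x.index if isinstance(x, pd.DataFrame) else None
    if hasattr(x, "toarray"):
        x = x.toarray()
    x = np.asarray(x, dtype=float)
    gene_names = list(gene_names)
    if x.shape[1] != len(gene_names):
        raise ValueError("gene_names length does not match matrix width")
    sigs = SignatureSet(signatures).intersect(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    ranks = _clipped_ranks(x, r_max)
    out = {}
    for name, genes in sigs.items():
        idx = [col[g] for g in genes]
        n = len(idx)
        u = ranks[:, idx].sum(axis=1) - n * (n + 1) / 2.0
        out[name] = np.maximum(0.0, 1.0 - u / (n * r_max))
    return pd.DataFrame(out, index=index)


def ucell_score(profile, gene_names, signature: list[str], r_max: int = 1500) -> float:
    """UCell score of a single cell profile for one signature."""
    scores = ucell_scores(
        np.asarray(profile, dtype=float)[None, :], gene_names, {"s": signature}, r_max
    )
    return float(scores["s"].iloc[0])


def shift_test(
    scores: pd.DataFrame,
    assignments: pd.Series,
    ntc_label: str = NONTARGETING,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Median score difference and Mann-Whitney p per (target, state) vs pooled NTC.

    ``assignments`` maps cell -> target gene, indexed like ``scores``; NTC
    cells are the reference group.  p-values are exact for small tie-free
    groups and tie-corrected asymptotic otherwise; BH is applied across the
    full target x state grid.  Groups below ``min_cells`` are flagged with
    p = NA and excluded from the BH family.
    """
    assignments = assignments.reindex(scores.index)
    ntc_mask = assignments == ntc_label
    if ntc_mask.sum() < min_cells:
        raise ValueError("too few non-targeting control cells")
    rows = []
    targets = sorted(t for t in assignments.dropna().unique() if t != ntc_label)
    for target in targets:
        mask = assignments == target
        for state in scores.columns:
            x = scores.loc[mask, state].to_numpy()
            y = scores.loc[ntc_mask, state].to_numpy()
            if len(x) < min_cells:
                rows.append(
                    {"target": target, "state": state, "n_perturbed": len(x),
                     "n_ntc": len(y), "median_diff": np.nan, "p_value": np.nan,
                     "flag": "too_few_cells"}
                )
                continue
            if np.array_equal(np.sort(x), np.sort(y)):
                # identical samples: no shift by construction
                med, p = 0.0, 1.0
            else:
                med = float(np.median(x) - np.median(y))
                _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            rows.append(
                {"target": target, "state": state, "n_perturbed": len(x),
                 "n_ntc": len(y), "median_diff": med, "p_value": float(p), "flag": ""}
            )
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["fdr"] = np.nan
    if valid.any():
        _, fdr, _, _ = multipletests(out.loc[valid, "p_value"].to_numpy(), method="fdr_bh")
        out.loc[valid, "fdr"] = fdr
    return out


def _percentiles_in(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Mid-rank percentile of each value within the reference distribution."""
    ref = np.sort(reference)
    below = np.searchsorted(ref, values, side="left")
    at_or_below = np.searchsorted(ref, values, side="right")
    return 100.0 * (below + 0.5 * (at_or_below - below)) / len(ref)


def percentile_shift(
    perturbed: np.ndarray,
    ntc: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    min_ntc: int = 20,
) -> dict:
    """Median percentile shift of perturbed scores within the NTC distribution.

    Each perturbed cell gets its mid-rank percentile among NTC scores; the
    shift is the median percentile minus 50 (bounded in [-50, +50]), with a
    95% percentile-bootstrap CI over perturbed cells.
    """
    perturbed = np.asarray(perturbed, dtype=float)
    ntc = np.asarray(ntc, dtype=float)
    if len(perturbed) == 0 or len(ntc) == 0:
        raise ValueError("empty group")
    if len(ntc) < min_ntc:
        raise ValueError(f"need >= {min_ntc} non-targeting cells for percentile shifts")
    pct = _percentiles_in(perturbed, ntc)
    shift = float(np.median(pct) - 50.0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = np.median(rng.choice(pct, size=len(pct), replace=True)) - 50.0
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"pct_shift": shift, "ci_low": float(lo), "ci_high": float(hi)}


class StateShiftModel:
    """Perturbation-vs-NTC shift statistics over a cells x states score matrix."""

    def __init__(self, scores: pd.DataFrame, assignments: pd.Series,
                 ntc_label: str = NONTARGETING):
        self.scores = scores
        self.assignments = assignments.reindex(scores.index)
        self.ntc_label = ntc_label

    def fit(self, n_boot: int = 1000, seed: int = 0, min_cells: int = 2) -> "ShiftResults":
        table = shift_test(self.scores, self.assignments, self.ntc_label, min_cells)
        ntc_mask = self.assignments == self.ntc_label
        rng = np.random.default_rng(seed)
        pct_cols = {"pct_shift": [], "ci_low": [], "ci_high": []}
        for _, row in table.iterrows():
            if row["flag"] or ntc_mask.sum() < 20:
                for k in pct_cols:
                    pct_cols[k].append(np.nan)
                continue
            res = percentile_shift(
                self.scores.loc[self.assignments == row["target"], row["state"]],
                self.scores.loc[ntc_mask, row["state"]],
                n_boot=n_boot,
                seed=rng,
            )
            for k in pct_cols:
                pct_cols[k].append(res[k])
        for k, v in pct_cols.items():
            table[k] = v
        return ShiftResults(table)


class ShiftResults:
    def __init__(self, table: pd.DataFrame):
        self.table = table

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            "State signature shifts vs non-targeting controls",
            "=" * 48,
            f"targets x states tested  {int(self.table['p_value'].notna().sum()):>6d}",
            f"significant at FDR<0.05  {len(sig):>6d}",
        ]
        for _, r in sig.sort_values("fdr").head(10).iterrows():
            lines.append(
                f"  {r['target']:<12s} {r['state']:<22s} "
                f"med_diff={r['median_diff']:+.3f}  fdr={r['fdr']:.2e}"
            )
        return "\n".join(lines)

    def plot_percentile_shifts(self, state: str | None = None, ax=None):
        """Median percentile shift per target with 95% CI error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        tab = self.table.dropna(subset=["pct_shift"])
        if state is not None:
            tab = tab[tab["state"] == state]
        tab = tab.sort_values("pct_shift")
        ypos = np.arange(len(tab))
        labels = (
            tab["target"] if state is not None else tab["target"] + " / " + tab["state"]
        )
        err = np.vstack(
            [tab["pct_shift"] - tab["ci_low"], tab["ci_high"] - tab["pct_shift"]]
        )
        ax.errorbar(tab["pct_shift"], ypos, xerr=err, fmt="o", ms=4, lw=1)
        ax.axvline(0, ls="--", lw=0.5, c="grey")
        ax.set_yticks(ypos, labels, fontsize=7)
        ax.set_xlabel("median percentile shift vs NTC")
        ax.set_xlim(-52, 52)
        return ax

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
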
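"""Continuous perturbation scores and score-weighted negative-binomial DE.

CRISPRi produces graded knockdown: cells carrying the same guide differ in
how strongly the target is repressed.  The analysis here (a Mixscale-style
construction) first finds an initial set of differentially expressed genes
(DEGs) for a target versus non-targeting control (NTC) cells, builds a
signed effect vector from them, projects every cell onto that vector to get
a continuous per-cell perturbation score, and finally uses the score both
as covariate and as regression weight in per-gene negative-binomial models,
so strongly perturbed cells dominate the fold-change estimate.

Entry point: :class:`PerturbationModel` -> :class:`PerturbationResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen import NONTARGETING

__all__ = [
    "EffectVector",
    "initial_deg_effect",
    "perturbation_score",
    "weighted_nb_de",
    "PerturbationModel",
    "PerturbationResults",
]


@dataclass
class EffectVector:
    """Signed per-gene effect of one target's knockdown.

    ``weights`` are mean log-normalised expression differences
    (perturbed - NTC) over the initial DEG set; empty iff no significant
    initial effect was found.
    """

    target: str
    deg_genes: list[str] = field(default_factory=list)
    weights: np.ndarray = field(default_factory=lambda: np.empty(0))
    has_effect: bool = False
    reason: str = ""


def _to_dense(x) -> np.ndarray:
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x, dtype=float)


def initial_deg_effect(
    lognorm: np.ndarray,
    gene_names,
    target_mask: np.ndarray,
    ntc_mask: np.ndarray,
    target: str,
    min_cells: int = 25,
    alpha: float = 0.05,
) -> EffectVector:
    """Initial DEG set and effect vector: per-gene Wilcoxon rank-sum of
    target vs NTC cells on log-normalised values, BH-corrected (FDR < alpha)."""
    lognorm = _to_dense(lognorm)
    gene_names = list(gene_names)
    n_target = int(target_mask.sum())
    if n_target < min_cells:
        return EffectVector(target=target, reason=f"only {n_target} cells (< {min_cells})")
    xt = lognorm[target_mask]
    xn = lognorm[ntc_mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give p = nan
        _, pvals = stats.mannwhitneyu(xt, xn, alternative="two-sided", axis=0)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    deg = fdr < alpha
    if not deg.any():
        return EffectVector(target=target, reason="no significant initial DEGs")
    diff = xt[:, deg].mean(axis=0) - xn[:, deg].mean(axis=0)
    return EffectVector(
        target=target,
        deg_genes=[g for g, d in zip(gene_names, deg) if d],
        weights=diff,
        has_effect=True,
    )


def perturbation_score(
    lognorm: np.ndarray,
    gene_names,
    effect: EffectVector,
    ntc_mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Project cells onto the effect vector and z-normalise against NTC cells.

    Raw score of cell c: s_c = sum_g w_g (x_cg - mean NTC_g) / sum_g w_g^2,
    over DEG genes only (genes outside the DEG set cannot move the score).
    Scores are then z-normalised by the mean/sd of NTC raw scores; reported
    NTC scores are fixed at 0 by definition.
    """
    if not effect.has_effect:
        raise ValueError(f"target {effect.target}: no effect vector ({effect.reason})")
    w = np.asarray(effect.weights, dtype=float)
    norm = float((w**2).sum())
    if norm == 0:
        raise ValueError("zero-norm effect vector")
    lognorm = _to_dense(lognorm)
    gene_names = list(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    idx = [col[g] for g in effect.deg_genes]
    sub = lognorm[:, idx]
    center = sub[ntc_mask].mean(axis=0)
    raw = (sub - center) @ w / norm
    ntc_raw = raw[ntc_mask]
    mu, sd = float(ntc_raw.mean()), float(ntc_raw.std(ddof=1))
    if sd == 0:
        raise ValueError("NTC projected scores have zero spread")
    z = (raw - mu) / sd
    out = pd.DataFrame({"raw_score": raw, "score": z})
    out["is_ntc"] = np.asarray(ntc_mask)
    out.loc[out["is_ntc"], "score"] = 0.0
    if cell_mask is not None:
        out = out[np.asarray(cell_mask) | out["is_ntc"]]
    return out


def _mom_dispersion(counts: np.ndarray, offset: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion on library-size-adjusted counts."""
    adj = counts / np.exp(offset - offset.mean())
    m = adj.mean()
    v = adj.var(ddof=1)
    if m <= 0:
        return floor
    return max((v - m) / m**2, floor)


def weighted_nb_de(
    counts: np.ndarray,
    gene_names,
    scores: np.ndarray,
    is_ntc: np.ndarray,
    target: str,
    weight_floor: float = 0.05,
    alpha: float = 0.05,
    weights: np.ndarray | None = None,
    dispersion: float | np.ndarray | None = None,
    offset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB regression of raw counts on the perturbation score.

    Model per gene: counts ~ NB(mu), log mu = b0 + beta * score + log(total
    counts).  Cell weights enter the likelihood: 1 for NTC cells and
    max(score, floor) normalised to mean 1 for perturbed cells, so strongly
    perturbed cells carry more information.  Wald p on beta, BH across
    genes; log2fc = beta * mean(perturbed score) * log2(e) (the fitted
    log-fold change at the average perturbed cell, in log2 units).

    ``dispersion`` fixes the per-gene NB dispersion (scalar or array);
    by default it is estimated per gene by method of moments.  With a fixed
    dispersion, beta estimates are invariant to uniform library-size
    rescaling through the offset; re-estimated dispersions make that
    invariance approximate.
    """
    counts = _to_dense(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("weighted_nb_de requires raw integer counts")
    scores = np.asarray(scores, dtype=float)
    is_ntc = np.asarray(is_ntc, dtype=bool)
    if offset is None:
        totals = counts.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("zero-total cell in count matrix")
        offset = np.log(totals)
    else:
        offset = np.asarray(offset, dtype=float)
    if weights is None:
        weights = np.ones(len(scores))
        pert = ~is_ntc
        w = np.maximum(scores[pert], weight_floor)
        weights[pert] = w / w.mean()
    design = sm.add_constant(scores)
    mean_pert_score = float(scores[~is_ntc].mean())
    rows = []
    for j, gene in enumerate(gene_names):
        y = counts[:, j]
        if y.sum() == 0 or np.all(y == y[0]):
            rows.append({"target": target, "gene": gene, "log2fc": np.nan,
                         "beta": np.nan, "p_value": np.nan, "flag": "constant"})
            continue
        if dispersion is None:
            disp = _mom_dispersion(y, offset)
        else:
            disp = float(np.atleast_1d(dispersion)[j % np.size(dispersion)])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, design,
                    family=sm.families.NegativeBinomial(alpha=disp),
                    offset=offset,
                    freq_weights=weights,
                )
                fit = model.fit(maxiter=100)
            if not np.isfinite(fit.params).all() or not np.isfinite(fit.bse).all():
                raise ValueError("non-finite fit")
            beta = float(fit.params[1])
            p = float(fit.pvalues[1])
            rows.append({
                "target": target, "gene": gene,
                "log2fc": beta * mean_pert_score / np.log(2),
                "beta": beta, "p_value": p, "flag": "",
            })
        except Exception:
            rows.append({"target": target, "gene": gene, "log2fc": np.nan,
                         "beta": np.nan, "p_value": np.nan, "flag": "no_convergence"})
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["fdr"] = np.nan
    if valid.any():
        _, fdr, _, _ = multipletests(out.loc[valid, "p_value"].to_numpy(), method="fdr_bh")
        out.loc[valid, "fdr"] = fdr
    return out


class PerturbationModel:
    """Score-weighted differential expression for one CRISPRi target.

    Parameters
    ----------
    counts
        cells x genes raw integer counts.
    lognorm
        matching log-normalised layer (used for the initial DEG test and the
        projection).
    gene_names, cell_targets
        feature names and the per-cell assigned target (``"non-targeting"``
        for control cells).
    target
        the perturbed gene to analyse.
    """

    def __init__(self, counts, lognorm, gene_names, cell_targets, target: str,
                 ntc_label: str = NONTARGETING):
        self.counts = counts
        self.lognorm = lognorm
        self.gene_names = list(gene_names)
        self.cell_targets = np.asarray(cell_targets)
        self.target = target
        self.ntc_label = ntc_label
        self.target_mask = self.cell_targets == target
        self.ntc_mask = self.cell_targets == ntc_label
        if not self.target_mask.any():
            raise ValueError(f"no cells assigned to {target!r}")
        if not self.ntc_mask.any():
            raise ValueError("no non-targeting control cells")

    def fit(self, min_cells: int = 25, alpha: float = 0.05,
            weight_floor: float = 0.05) -> "PerturbationResults":
        effect = initial_deg_effect(
            self.lognorm, self.gene_names, self.target_mask, self.ntc_mask,
            self.target, min_cells=min_cells, alpha=alpha,
        )
        keep = self.target_mask | self.ntc_mask
        counts = _to_dense(self.counts)[keep]
        is_ntc = self.ntc_mask[keep]
        if effect.has_effect:
            score_tab = perturbation_score(
                self.lognorm, self.gene_names, effect, self.ntc_mask
            )
            scores = score_tab["score"].to_numpy()[keep]
            de = weighted_nb_de(
                counts, self.gene_names, scores, is_ntc, self.target,
                weight_floor=weight_floor, alpha=alpha,
            )
        else:
            # standard two-group NB DE: binary covariate, unit weights
            score_tab = None
            indicator = (~is_ntc).astype(float)
            de = weighted_nb_de(
                counts, self.gene_names, indicator, is_ntc, self.target,
                alpha=alpha, weights=np.ones(len(indicator)),
            )
        return PerturbationResults(self.target, effect, score_tab, de)


class PerturbationResults:
    """Effect vector, per-cell scores and the DE table for one target."""

    def __init__(self, target, effect: EffectVector, scores, de_table: pd.DataFrame):
        self.target = target
        self.effect = effect
        self.scores = scores
        self.de_table = de_table

    def degs(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.de_table[self.de_table["fdr"] < fdr].sort_values("fdr")

    def heatmap_order(self) -> np.ndarray | None:
        """Cell order for expression heatmaps: by score with a floor of 0."""
        if self.scores is None:
            return None
        return np.argsort(np.maximum(self.scores["score"].to_numpy(), 0.0))

    def top_degs(self, n_each: int = 25, fdr: float = 0.05) -> pd.DataFrame:
        """Top up- and down-regulated DEGs by FDR (heatmap convention)."""
        sig = self.degs(fdr)
        up = sig[sig["beta"] > 0].head(n_each)
        down = sig[sig["beta"] <= 0].head(n_each)
        return pd.concat([up, down], ignore_index=True)

    def summary(self) -> str:
        sig = self.degs() if self.de_table["fdr"].notna().any() else self.de_table.iloc[:0]
        lines = [
            f"Perturbation DE: {self.target}",
            "=" * 40,
            f"initial effect         {'yes' if self.effect.has_effect else 'no (' + self.effect.reason + ')'}",
            f"initial DEG set size   {len(self.effect.deg_genes):>6d}",
            f"genes tested           {int(self.de_table['p_value'].notna().sum()):>6d}",
            f"DEGs at FDR<0.05       {len(sig):>6d}",
        ]
        return "\n".join(lines)
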
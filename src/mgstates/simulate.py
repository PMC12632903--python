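"""Synthetic datasets with planted ground truth for every pipeline stage.

Three generators mirror the three experimental arms:

* :func:`simulate_screen` — multinomial sgRNA counts from a two-bin sort,
  with per-gene sorting biases entering through a logistic shift of each
  guide's probability of landing in the high bin.
* :func:`simulate_cropseq` — negative-binomial single-cell RNA counts with
  per-target DEG effect vectors scaled by graded per-cell knockdown
  multipliers, optional state-signature latents and ADT proteins tracking
  them, plus guide-UMI tables with ambient background and planted doublets.
* :func:`simulate_methylation` — binomial CpG methylation counts split by
  strand and technical replicate, with planted promoter-level differences.

Every generator returns a :class:`SimTruth` carrying the planted parameters;
end-to-end tests read truth only from it, never from pipeline output.  The
same seed regenerates identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .screen import NONTARGETING

__all__ = ["SimTruth", "simulate_screen", "simulate_cropseq", "simulate_methylation"]


@dataclass
class SimTruth:
    """Planted ground truth serialized next to every generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "seed": self.seed, "params": self.params,
                 "truth": self.truth},
                default=default, indent=1, sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_screen(
    n_genes: int = 1619,
    sgrnas_per_gene: int = 5,
    n_ntc: int = 250,
    depth: int = 2_000_000,
    effect_spec: dict[str, float] | None = None,
    dirichlet_conc: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Two-bin sorted screen counts with planted per-gene sorting biases.

    Guide abundances are Dirichlet-distributed; a gene with logistic shift s
    sends each of its guides' cells to the high bin with probability
    expit(s) instead of 1/2; per-bin counts are multinomial at ``depth``
    reads.  ``effect_spec`` maps gene name -> shift (genes default to 0,
    i.e. a calibrated null screen).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    effect_spec = dict(effect_spec or {})
    unknown = set(effect_spec) - set(genes)
    if unknown:
        raise ValueError(f"effect_spec refers to unknown genes: {sorted(unknown)[:5]}")

    sgrna_ids, sgrna_genes, shifts = [], [], []
    for g in genes:
        s = float(effect_spec.get(g, 0.0))
        for j in range(sgrnas_per_gene):
            sgrna_ids.append(f"{g}_g{j + 1}")
            sgrna_genes.append(g)
            shifts.append(s)
    for j in range(n_ntc):
        sgrna_ids.append(f"{NONTARGETING}_{j + 1:04d}")
        sgrna_genes.append(NONTARGETING)
        shifts.append(0.0)
    shifts = np.asarray(shifts)

    abund = rng.dirichlet(np.full(len(sgrna_ids), dirichlet_conc))
    q_high = _expit(shifts)
    p_high = abund * q_high
    p_low = abund * (1.0 - q_high)
    count_high = rng.multinomial(depth, p_high / p_high.sum())
    count_low = rng.multinomial(depth, p_low / p_low.sum())

    counts = pd.DataFrame(
        {"sgrna_id": sgrna_ids, "gene": sgrna_genes,
         "count_high": count_high, "count_low": count_low}
    )
    truth = SimTruth(
        kind="screen", seed=seed,
        params={"n_genes": n_genes, "sgrnas_per_gene": sgrnas_per_gene,
                "n_ntc": n_ntc, "depth": depth, "dirichlet_conc": dirichlet_conc},
        truth={"effects": effect_spec},
    )
    return counts, truth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_cropseq(
    n_cells: int = 2000,
    n_genes: int = 300,
    targets_spec: dict[str, dict] | None = None,
    n_ntc_guides: int = 5,
    guides_per_target: int = 2,
    ambient_rate: float = 0.05,
    doublet_rate: float = 0.05,
    nb_dispersion: float = 0.3,
    adt_dispersion: float = 0.5,
    state_spec: dict[str, dict] | None = None,
    adt_spec: dict[str, dict] | None = None,
    mean_depth: float = 5000.0,
    guide_umi_rate: float = 20.0,
    state_slope: float = 1.2,
    seed: int = 0,
) -> dict:
    """Paired RNA/ADT count matrices and guide-UMI tables with planted truth.

    targets_spec maps target name -> options:
      ``n_deg`` (default 30) planted DEG count, ``log_fc`` (default 1.0)
      natural-log effect magnitude (signs random), ``multipliers`` an
      explicit per-cell knockdown-multiplier pool (default Gamma(4, 1/4),
      mean 1 — graded knockdown).
    state_spec maps state name -> ``{"n_genes": int, "target_effects":
      {target: delta}}``: state genes share a per-cell N(0,1) latent
      activity shifted by delta in that target's cells and modulating their
      log-mean with slope ``state_slope``.
    adt_spec maps protein -> ``{"state": name, "r": float}``: the protein's
      log-level tracks the state latent with the planted correlation.

    Returns a dict with ``rna`` (AnnData; raw counts in .X, truth columns in
    .obs), ``adt`` (AnnData or None), ``guide_umis`` (DataFrame) and
    ``truth`` (SimTruth).
    """
    rng = np.random.default_rng(seed)
    targets_spec = dict(targets_spec or {})
    state_spec = dict(state_spec or {})
    adt_spec = dict(adt_spec or {})
    gene_names = [f"G{i + 1:05d}" for i in range(n_genes)]

    guides, guide_target = [], {}
    for t in targets_spec:
        for j in range(guides_per_target):
            gid = f"{t}_g{j + 1}"
            guides.append(gid)
            guide_target[gid] = t
    for j in range(n_ntc_guides):
        gid = f"{NONTARGETING}_g{j + 1}"
        guides.append(gid)
        guide_target[gid] = NONTARGETING
    if not guides:
        raise ValueError("no guides: provide targets_spec and/or n_ntc_guides")

    true_guide = rng.choice(guides, size=n_cells)
    is_doublet = rng.random(n_cells) < doublet_rate
    second_guide = np.array([
        rng.choice([g for g in guides if g != tg]) if d else ""
        for tg, d in zip(true_guide, is_doublet)
    ])
    cell_target = np.array([guide_target[g] for g in true_guide])

    # planted effect vectors and per-cell knockdown multipliers
    effects, multipliers = {}, np.zeros(n_cells)
    for t, spec in targets_spec.items():
        n_deg = int(spec.get("n_deg", 30))
        log_fc = float(spec.get("log_fc", 1.0))
        idx = rng.choice(n_genes, size=n_deg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_deg)
        effects[t] = {"genes": [gene_names[i] for i in idx],
                      "delta": (signs * log_fc).tolist(), "idx": idx}
        mask = cell_target == t
        pool = spec.get("multipliers")
        if pool is None:
            multipliers[mask] = rng.gamma(4.0, 0.25, size=mask.sum())
        else:
            pool = np.asarray(pool, dtype=float)
            multipliers[mask] = pool[np.arange(mask.sum()) % len(pool)]

    # state latents
    state_genes, activities = {}, {}
    for s, spec in state_spec.items():
        n_sg = int(spec.get("n_genes", 20))
        idx = rng.choice(n_genes, size=n_sg, replace=False)
        state_genes[s] = idx
        a = rng.normal(size=n_cells)
        for t, delta in spec.get("target_effects", {}).items():
            a[cell_target == t] += float(delta)
        activities[s] = a

    base_p = rng.lognormal(0.0, 1.0, size=n_genes)
    base_p /= base_p.sum()
    depth = rng.lognormal(np.log(mean_depth), 0.15, size=n_cells)
    log_mu = np.log(np.outer(depth, base_p))
    for t, eff in effects.items():
        mask = cell_target == t
        log_mu[np.ix_(mask, eff["idx"])] += (
            multipliers[mask, None] * np.asarray(eff["delta"])[None, :]
        )
    for s, idx in state_genes.items():
        log_mu[:, idx] += state_slope * activities[s][:, None]
    rna = _nb_counts(rng, np.exp(log_mu), nb_dispersion)

    adata = ad.AnnData(
        X=rna,
        obs=pd.DataFrame(
            {"true_guide": true_guide, "true_target": cell_target,
             "is_doublet": is_doublet, "knockdown_multiplier": multipliers},
            index=[f"CELL{i + 1:05d}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=gene_names),
    )
    for s, a in activities.items():
        adata.obs[f"activity_{s}"] = a

    adt = None
    planted_r = {}
    if adt_spec:
        cols = {}
        for protein, spec in adt_spec.items():
            r = float(spec["r"])
            if not -1.0 < r < 1.0:
                raise ValueError("planted ADT correlation must lie in (-1, 1)")
            a = activities[spec["state"]]
            za = (a - a.mean()) / a.std()
            # amplitude chosen so the measured log-level correlates with the
            # state activity at the planted r, absorbing NB counting noise
            # (log-scale noise variance ~ dispersion + 1/mu)
            mu0 = 500.0
            noise_var = adt_dispersion + 1.0 / mu0
            amp = np.sign(r) * np.sqrt(noise_var * r**2 / (1.0 - r**2))
            mu = np.exp(np.log(mu0) + amp * za)
            cols[protein] = _nb_counts(rng, mu, adt_dispersion)
            planted_r[protein] = {"state": spec["state"], "r": r}
        adt = ad.AnnData(
            X=np.column_stack(list(cols.values())),
            obs=pd.DataFrame(index=adata.obs_names),
            var=pd.DataFrame(index=list(cols.keys())),
        )

    # guide UMIs: true guide(s) + ambient background at the library frequency
    rows = []
    lib_freq = np.full(len(guides), 1.0 / len(guides))
    for i, cell in enumerate(adata.obs_names):
        umis = {}
        umis[true_guide[i]] = 1 + rng.poisson(guide_umi_rate - 1)
        if is_doublet[i]:
            umis[second_guide[i]] = umis.get(second_guide[i], 0) + 1 + rng.poisson(
                guide_umi_rate - 1
            )
        n_amb = rng.poisson(ambient_rate * guide_umi_rate)
        if n_amb > 0:
            amb = rng.multinomial(n_amb, lib_freq)
            for g, c in zip(guides, amb):
                if c > 0:
                    umis[g] = umis.get(g, 0) + int(c)
        for g, c in umis.items():
            rows.append({"cell_barcode": cell, "sgrna_id": g, "umi_count": int(c)})
    guide_umis = pd.DataFrame(rows)

    truth = SimTruth(
        kind="cropseq", seed=seed,
        params={"n_cells": n_cells, "n_genes": n_genes,
                "ambient_rate": ambient_rate, "doublet_rate": doublet_rate,
                "nb_dispersion": nb_dispersion, "state_slope": state_slope},
        truth={
            "guide_target": guide_target,
            "cells": {
                "true_guide": true_guide.tolist(),
                "is_doublet": is_doublet.tolist(),
                "true_target": cell_target.tolist(),
                "knockdown_multiplier": multipliers.tolist(),
            },
            "effects": {
                t: {"genes": e["genes"], "delta": e["delta"]} for t, e in effects.items()
            },
            "state_genes": {s: [gene_names[i] for i in idx] for s, idx in state_genes.items()},
            "adt": planted_r,
        },
    )
    return {"rna": adata, "adt": adt, "guide_umis": guide_umis, "truth": truth}


def simulate_methylation(
    n_promoters: int = 200,
    cpgs_per_promoter: int = 8,
    n_background_cpgs: int = 2000,
    region_diffs: dict[int, float] | None = None,
    baseline_alpha: float = 7.0,
    baseline_beta: float = 3.0,
    coverage: float = 30.0,
    n_samples: int = 2,
    n_replicates: int = 2,
    window: int = 500,
    seed: int = 0,
) -> dict:
    """Strand- and replicate-split binomial CpG tables with planted promoter effects.

    ``region_diffs`` maps promoter index -> methylation difference planted in
    the condition samples (proportion scale, applied to every CpG in the
    promoter window).  Per-CpG baselines are Beta(alpha, beta) shared across
    samples; coverage per (sample, replicate, strand) slice is Poisson with
    mean coverage / (n_replicates * 2), so a sample's strand-combined,
    replicate-merged coverage is Poisson(``coverage``).

    Returns ``{"condition": ..., "control": ...}`` nested as
    tables[group][sample][replicate][strand], plus ``tss`` (BED-ready
    DataFrame), and ``truth``.
    """
    rng = np.random.default_rng(seed)
    region_diffs = dict(region_diffs or {})
    bad = [i for i in region_diffs if not 0 <= i < n_promoters]
    if bad:
        raise ValueError(f"region_diffs indices out of range: {bad[:5]}")

    spacing = 10 * (2 * window)
    tss_rows, cpg_pos, cpg_promoter = [], [], []
    for i in range(n_promoters):
        tss = spacing * (i + 1)
        strand = "+" if i % 2 == 0 else "-"
        tss_rows.append({"gene": f"PROM{i + 1:04d}", "chrom": "chr1",
                         "tss": tss, "strand": strand})
        offs = rng.choice(np.arange(-window, window + 1, 2), size=cpgs_per_promoter,
                          replace=False)
        for o in np.sort(offs):
            cpg_pos.append(tss + int(o))
            cpg_promoter.append(i)
    bg_lo = spacing * (n_promoters + 2)
    bg = np.sort(rng.choice(
        np.arange(bg_lo, bg_lo + 40 * n_background_cpgs, 2),
        size=n_background_cpgs, replace=False,
    ))
    cpg_pos.extend(int(p) for p in bg)
    cpg_promoter.extend([-1] * n_background_cpgs)
    cpg_pos = np.asarray(cpg_pos)
    cpg_promoter = np.asarray(cpg_promoter)

    diff = np.array([region_diffs.get(p, 0.0) for p in cpg_promoter])
    if (diff <= -1).any() or (diff >= 1).any():
        raise ValueError("planted differences must lie in (-1, 1)")
    # baselines ~ Beta, truncated per CpG to the range compatible with the
    # planted difference (baseline + diff must stay inside [0, 1])
    lo = np.maximum(0.005, -diff + 0.005)
    hi = np.minimum(0.995, 1.0 - diff - 0.005)
    u = rng.uniform(
        stats.beta.cdf(lo, baseline_alpha, baseline_beta),
        stats.beta.cdf(hi, baseline_alpha, baseline_beta),
    )
    baseline = stats.beta.ppf(u, baseline_alpha, baseline_beta)
    shifted = baseline + diff
    p_cond = np.clip(shifted, 0.005, 0.995)
    p_ctrl = np.clip(baseline, 0.005, 0.995)

    slice_cov = coverage / (n_replicates * 2)
    tables: dict[str, list] = {"condition": [], "control": []}
    for group, p in (("condition", p_cond), ("control", p_ctrl)):
        for _s in range(n_samples):
            sample = []
            for _r in range(n_replicates):
                reps = {}
                for strand in ("top", "bottom"):
                    cov = rng.poisson(slice_cov, size=len(cpg_pos))
                    meth = rng.binomial(cov, p)
                    pos = cpg_pos if strand == "top" else cpg_pos + 1
                    reps[strand] = pd.DataFrame(
                        {"chrom": "chr1", "pos": pos, "total": cov, "meth": meth}
                    )
                sample.append(reps)
            tables[group].append(sample)

    tss = pd.DataFrame(tss_rows)
    truth = SimTruth(
        kind="methylation", seed=seed,
        params={"n_promoters": n_promoters, "cpgs_per_promoter": cpgs_per_promoter,
                "coverage": coverage, "window": window},
        truth={
            "region_diffs": {tss_rows[i]["gene"]: d for i, d in region_diffs.items()},
            "baseline_mean": float(baseline.mean()),
        },
    )
    return {"tables": tables, "tss": tss, "truth": truth}
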
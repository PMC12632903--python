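"""Screen enrichment statistics against direct-formula and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mgstates.screen import (
    NONTARGETING,
    ScreenEnrichment,
    build_quasi_genes,
    call_hits,
    cross_screen_summary,
    gene_aggregate_drop_first,
    normalize_and_ratio,
    ntc_null,
)
from mgstates.simulate import simulate_screen


class TestNormalizeAndRatio:
    def test_symmetric_counts_give_zero(self):
        df = pd.DataFrame(
            {"sgrna_id": ["a", "b"], "gene": ["G", "G"],
             "count_high": [100, 100], "count_low": [100, 100]}
        )
        out = normalize_and_ratio(df, pseudocount=0.5)
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_doubling_gives_log2_one_at_vanishing_pseudocount(self):
        df = pd.DataFrame(
            {"sgrna_id": ["a", "b"], "gene": ["G", "G"],
             "count_high": [200, 100], "count_low": [100, 200]}
        )
        out = normalize_and_ratio(df, pseudocount=1e-9)
        assert out["log2_ratio"].iloc[0] == pytest.approx(1.0, abs=1e-7)

    def test_matches_direct_formula_oracle(self, toy_screen_counts):
        pc = 0.5
        out = normalize_and_ratio(toy_screen_counts, pc)
        th = toy_screen_counts["count_high"].sum()
        tl = toy_screen_counts["count_low"].sum()
        for _, row in toy_screen_counts.head(6).iterrows():
            expected = np.log2(
                ((row["count_high"] + pc) / th) / ((row["count_low"] + pc) / tl)
            )
            got = out.loc[out["sgrna_id"] == row["sgrna_id"], "log2_ratio"].iloc[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_rejects_empty_and_bad_pseudocount(self):
        with pytest.raises(ValueError):
            normalize_and_ratio(pd.DataFrame(columns=["sgrna_id", "gene", "count_high", "count_low"]))
        df = pd.DataFrame({"sgrna_id": ["a"], "gene": ["G"], "count_high": [1], "count_low": [1]})
        with pytest.raises(ValueError):
            normalize_and_ratio(df, pseudocount=0)


class TestNtcNull:
    def _phen(self, ntc_ratios, extra=()):
        rows = [
            {"sgrna_id": f"n{i}", "gene": NONTARGETING, "log2_ratio": r}
            for i, r in enumerate(ntc_ratios)
        ]
        rows += [
            {"sgrna_id": f"t{i}", "gene": "T", "log2_ratio": r}
            for i, r in enumerate(extra)
        ]
        return pd.DataFrame(rows)

    def test_constant_ntc_raises(self):
        with pytest.raises(ValueError, match="zero spread"):
            ntc_null(self._phen([0.1] * 25))

    def test_outlier_removed_and_sd_shrinks(self, rng):
        tight = rng.normal(0, 0.1, 249)
        phen = self._phen(np.append(tight, 5.0))
        scored, null = ntc_null(phen, z_cutoff=5)
        # oracle: recompute sd with and without the flagged entry
        sd_all = np.std(np.append(tight, 5.0), ddof=1)
        assert abs(5.0 / sd_all) > 5  # it is flagged
        assert null.removed_ids == ["n249"]
        assert null.sd == pytest.approx(np.std(tight, ddof=1), rel=1e-12)
        assert null.sd < sd_all

    def test_z_is_ratio_over_retained_sd(self, rng):
        ntc = rng.normal(0, 0.2, 50)
        phen = self._phen(ntc, extra=[2 * np.std(ntc, ddof=1)])
        scored, null = ntc_null(phen)
        z = scored.loc[scored["gene"] == "T", "z_phenotype"].iloc[0]
        assert z == pytest.approx(2.0, rel=1e-9)
        p = scored.loc[scored["gene"] == "T", "p_value"].iloc[0]
        assert p == pytest.approx(2 * stats.norm.sf(2.0), rel=1e-9)

    def test_too_few_ntcs(self):
        with pytest.raises(ValueError, match="non-targeting"):
            ntc_null(self._phen([0.0, 0.1, 0.2]))


class TestQuasiGenes:
    def test_exhaustive_singletons(self):
        ids = [f"n{i}" for i in range(10)]
        groups = build_quasi_genes(ids, group_size=1, exhaustive=True)
        assert sorted(g[0] for g in groups.values()) == sorted(ids)

    def test_same_seed_reproducible(self):
        ids = [f"n{i}" for i in range(50)]
        a = build_quasi_genes(ids, 5, 100, seed=7)
        b = build_quasi_genes(ids, 5, 100, seed=7)
        assert a == b

    def test_no_within_group_repeats_at_scale(self):
        ids = [f"n{i}" for i in range(250)]
        groups = build_quasi_genes(ids, group_size=5, n_quasi=1000, seed=0)
        assert len(groups) == 1000
        for members in groups.values():
            assert len(members) == 5
            assert len(set(members)) == 5
            assert set(members) <= set(ids)

    def test_group_size_exceeding_pool(self):
        with pytest.raises(ValueError):
            build_quasi_genes(["a", "b"], group_size=3)


class TestDropFirstAggregation:
    def _guides(self, zs, ratios=None):
        ratios = zs if ratios is None else ratios
        return pd.DataFrame(
            {"sgrna_id": [f"g{i}" for i in range(len(zs))],
             "gene": "T", "log2_ratio": ratios, "z_phenotype": zs}
        )

    def test_identical_z_mean_unchanged(self):
        rec = gene_aggregate_drop_first(self._guides([1.0] * 5))
        assert rec["z_combined"] == pytest.approx(4 / np.sqrt(4))
        assert rec["log2fc"] == pytest.approx(1.0)

    def test_drops_largest_abs_z(self):
        rec = gene_aggregate_drop_first(self._guides([3.0, 1.0, 1.0, 1.0, 0.0]))
        # drop the 3; remaining mean z = 0.75
        assert rec["z_combined"] == pytest.approx(3.0 / np.sqrt(4))
        assert rec["log2fc"] == pytest.approx(0.75)

    def test_negative_extreme_is_dropped(self):
        rec = gene_aggregate_drop_first(self._guides([-4.0, 1.0, 1.0]))
        assert rec["log2fc"] == pytest.approx(1.0)

    def test_single_guide_flagged_not_dropped(self):
        rec = gene_aggregate_drop_first(self._guides([2.0]))
        assert rec["single_guide"]
        assert rec["z_combined"] == pytest.approx(2.0)

    def test_stouffer_matches_bruteforce_oracle(self, rng):
        # 50 genes x 5 guides; oracle recomputes the combination per gene
        for _ in range(50):
            z = rng.normal(0, 2, size=5)
            rec = gene_aggregate_drop_first(self._guides(z))
            kept = np.delete(z, np.argmax(np.abs(z)))
            z_comb = kept.sum() / np.sqrt(len(kept))
            p = 2 * stats.norm.sf(abs(z_comb))
            assert rec["z_combined"] == pytest.approx(z_comb, rel=1e-12)
            assert rec["p_value"] == pytest.approx(p, rel=1e-9)


class TestCallHits:
    def _genes(self, ps, quasi=None):
        quasi = quasi or [False] * len(ps)
        return pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(ps))], "p_value": ps,
             "log2fc": np.linspace(-1, 1, len(ps)), "is_quasi": quasi}
        )

    def test_all_p_one_gives_zero_hits(self):
        out = call_hits(self._genes([1.0] * 6), fdr_threshold=0.05)
        assert not out["is_hit"].any()

    def test_bh_matches_hand_oracle(self):
        ps = [0.001, 0.02, 0.04, 0.5]
        out = call_hits(self._genes(ps), fdr_threshold=0.05)
        # oracle: sort, p*(n/rank), enforce monotonicity from the bottom
        n = len(ps)
        order = np.argsort(ps)
        raw = np.array(ps)[order] * n / (np.arange(n) + 1)
        adj = np.minimum.accumulate(raw[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj, 1.0)
        assert np.allclose(out["fdr"], expected)

    def test_quasi_genes_in_family_but_not_hits(self):
        out = call_hits(
            self._genes([1e-6, 1e-6, 0.9], quasi=[False, True, False]),
            fdr_threshold=0.05,
        )
        assert out.loc[out["is_quasi"], "is_hit"].eq(False).all()
        assert out.loc[~out["is_quasi"], "is_hit"].tolist() == [True, False]

    def test_phenotype_score_variants(self):
        base = self._genes([0.01, 0.5])
        default = call_hits(base)
        literal = call_hits(base, literal_phenotype_score=True)
        assert np.allclose(
            default["phenotype_score"], default["log2fc"] * (-np.log10(default["fdr"]))
        )
        assert np.allclose(literal["phenotype_score"], literal["log2fc"] * literal["fdr"])


class TestCrossScreenSummary:
    def _tab(self, hits_fc: dict):
        return pd.DataFrame(
            {"gene": list(hits_fc), "log2fc": list(hits_fc.values()),
             "is_hit": True, "is_quasi": False}
        )

    def test_disjoint_hits_all_single_state(self):
        per_gene, pairs = cross_screen_summary(
            {"s1": self._tab({"A": 1.0}), "s2": self._tab({"B": -1.0})}
        )
        assert (per_gene["n_screens"] == 1).all()
        assert pairs["n_overlap"].iloc[0] == 0

    def test_identical_hits_flipped_signs(self):
        per_gene, pairs = cross_screen_summary(
            {"s1": self._tab({"A": 1.0, "B": 2.0}),
             "s2": self._tab({"A": -1.0, "B": -0.5})}
        )
        assert (per_gene["n_screens"] == 2).all()
        assert pairs["n_overlap"].iloc[0] == 2
        assert pairs["frac_opposing"].iloc[0] == 1.0

    def test_three_screens_match_set_algebra_oracle(self):
        tabs = {
            "s1": self._tab({"A": 1, "B": 1, "C": 1}),
            "s2": self._tab({"B": -1, "C": 1, "D": 1}),
            "s3": self._tab({"C": -1}),
        }
        per_gene, pairs = cross_screen_summary(tabs)
        counts = dict(zip(per_gene["gene"], per_gene["n_screens"]))
        assert counts == {"A": 1, "B": 2, "C": 3, "D": 1}
        p12 = pairs[(pairs.screen_a == "s1") & (pairs.screen_b == "s2")].iloc[0]
        assert p12["n_overlap"] == 2 and p12["frac_opposing"] == 0.5


class TestScreenModel:
    def test_oracle_equivalence_on_fixed_input(self, toy_screen_counts):
        """sgRNA z and p match the direct-formula chain to 1e-9."""
        res = ScreenEnrichment(toy_screen_counts).fit(n_quasi=20, seed=0)
        pc = 0.5
        th = toy_screen_counts["count_high"].sum()
        tl = toy_screen_counts["count_low"].sum()
        ratios = np.log2(
            ((toy_screen_counts["count_high"] + pc) / th)
            / ((toy_screen_counts["count_low"] + pc) / tl)
        )
        ntc = ratios[toy_screen_counts["gene"] == NONTARGETING]
        sd0 = ntc.std(ddof=1)
        retained = ntc[(ntc / sd0).abs() <= 5]
        sd = retained.std(ddof=1)
        np.testing.assert_allclose(
            res.sgrna_table["z_phenotype"], ratios / sd, atol=1e-9
        )
        np.testing.assert_allclose(
            res.sgrna_table["p_value"],
            np.clip(2 * stats.norm.sf(np.abs(ratios / sd)), 1e-300, 1),
            rtol=1e-9,
        )

    def test_planted_bias_monotonicity(self):
        """Stronger planted sorting bias never shrinks |gene log2fc| (paired sims)."""
        fcs = []
        for shift in (0.5, 1.0, 1.5):
            counts, _ = simulate_screen(
                n_genes=80, depth=400_000, effect_spec={"GENE0001": shift}, seed=42
            )
            res = ScreenEnrichment(counts).fit(n_quasi=50, seed=1)
            fcs.append(
                abs(res.targeting.set_index("gene").loc["GENE0001", "log2fc"])
            )
        assert fcs[0] < fcs[1] < fcs[2]

    def test_summary_and_export(self, toy_screen_counts, tmp_path):
        res = ScreenEnrichment(toy_screen_counts).fit(n_quasi=10, seed=0)
        assert "quasi-genes" in res.summary()
        res.to_tsv(tmp_path)
        assert (tmp_path / "gene_results.tsv").exists()
        back = pd.read_csv(tmp_path / "gene_results.tsv", sep="\t")
        assert {"fc", "log2fc", "p_value", "fdr", "phenotype_score"} <= set(back.columns)


def test_volcano_plot_returns_axes(toy_screen_counts):
    import matplotlib

    matplotlib.use("Agg")
    res = ScreenEnrichment(toy_screen_counts).fit(n_quasi=10, seed=0)
    ax = res.plot_volcano()
    assert ax.get_xlabel().startswith("knockdown")
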
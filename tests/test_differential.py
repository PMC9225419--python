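import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from microsev.io import RANKS, CountTable, SampleMetadata, TaxonomyTable
from microsev.differential import bh_fdr, summarize_level, taxon_test, tsd
from microsev.synthetic import SyntheticCohortSpec, default_paper_like_spec, generate
from microsev.transforms import aggregate_to_level, clr, rank_columns

from conftest import make_metadata


def brute_force_bh(p):
    """Independent step-up implementation: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        q[order[i]] = min(running_min, 1.0)
    return q


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_fdr([np.nan, 0.1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 200)))
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_idempotent_safe(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (bh_fdr(q) >= q - 1e-12).all()


def _null_ranks(rng, md, n_taxa=20):
    y = rng.normal(size=(len(md.sample_ids), n_taxa))
    return pd.DataFrame(y, index=md.sample_ids,
                        columns=[f"g{j}" for j in range(n_taxa)]).rank(axis=0)


class TestTaxonTest:
    def test_planted_monotone_detected_by_both_contrasts(self):
        rng = np.random.default_rng(1)
        md = make_metadata(["HC"] * 23 + ["ASYM_UAS"] * 43 + ["SS_SLE"] * 82)
        score = md.severity_score().to_numpy()
        y = rng.normal(size=(148, 5))
        y[:, 0] += 1.5 * score
        ranks = pd.DataFrame(y, index=md.sample_ids,
                             columns=list("abcde")).rank(axis=0)
        res_o = taxon_test(ranks, md, "ordinal3")
        res_d = taxon_test(ranks, md, "discrete3")
        assert res_o.loc["a", "p_value"] < 1e-6 and res_o.loc["a", "estimate"] > 0
        assert res_d.loc["a", "p_value"] < 1e-4
        assert (res_o.loc[list("bcde"), "p_value"] > 0.001).all()

    def test_nonmonotone_favors_discrete(self):
        """Low-high-low pattern: 2-df F rejects more often than the trend."""
        rng = np.random.default_rng(2)
        md = make_metadata(["HC"] * 20 + ["ASYM_UAS"] * 20 + ["SS_SLE"] * 20)
        grp = md.group.to_numpy()
        bump = np.where(grp == "ASYM_UAS", 1.2, 0.0)
        wins_d = wins_o = 0
        for _ in range(300):
            y = rng.normal(size=60) + bump
            ranks = pd.DataFrame({"g": y, "h": rng.normal(size=60)},
                                 index=md.sample_ids).rank(axis=0)
            wins_o += taxon_test(ranks, md, "ordinal3").loc["g", "p_value"] < 0.05
            wins_d += taxon_test(ranks, md, "discrete3").loc["g", "p_value"] < 0.05
        assert wins_d > wins_o

    def test_constant_ranks_get_p_one(self):
        md = make_metadata(["HC"] * 4 + ["ASYM_UAS"] * 4 + ["SS_SLE"] * 4)
        ranks = pd.DataFrame(
            {"flat": np.full(12, 6.5), "var": np.arange(12.0) + 1},
            index=md.sample_ids,
        )
        with pytest.warns(UserWarning, match="constant ranks"):
            res = taxon_test(ranks, md, "ordinal3")
        assert res.loc["flat", "p_value"] == 1.0
        assert res.loc["flat", "estimate"] == 0.0

    def test_matches_statsmodels_per_taxon(self):
        """Cross-check the vectorized GLM against statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        md = make_metadata(["HC"] * 10 + ["ASYM_UAS"] * 10 + ["SS_SLE"] * 10)
        ranks = _null_ranks(rng, md, n_taxa=5)
        res = taxon_test(ranks, md, "ordinal3", batch=True)
        score = md.severity_score().to_numpy()
        B = pd.get_dummies(md.batch, drop_first=True, dtype=float).to_numpy()
        X = sm.add_constant(np.column_stack([score, B]))
        for tx in ranks.columns:
            fit = sm.OLS(ranks[tx].to_numpy(), X).fit()
            assert res.loc[tx, "estimate"] == pytest.approx(fit.params[1], rel=1e-9)
            assert res.loc[tx, "p_value"] == pytest.approx(fit.pvalues[1], rel=1e-9)

    def test_pooled_two_group_equals_merged_label(self):
        rng = np.random.default_rng(6)
        md = make_metadata(["HC"] * 15 + ["ASYM_UAS"] * 15 + ["SS_SLE"] * 15)
        ranks = _null_ranks(rng, md, n_taxa=4)
        res = taxon_test(ranks, md, "two_group",
                         two_group=("HC", ("ASYM_UAS", "SS_SLE")))
        merged = md.data.copy()
        merged.loc[merged["group"] == "SS_SLE", "group"] = "ASYM_UAS"
        res2 = taxon_test(ranks, SampleMetadata(merged), "two_group",
                          two_group=("HC", "ASYM_UAS"))
        np.testing.assert_allclose(res["p_value"], res2["p_value"], atol=1e-12)


class TestTsd:
    def _cohort(self, seed=0, planted=(), base_logsd=2.0, small_phyla=False):
        shape = ({"phylum": 6, "class": 8, "order": 12, "family": 20,
                  "genus": 30} if small_phyla else
                 {"phylum": 3, "class": 5, "order": 8, "family": 15,
                  "genus": 30})
        spec = SyntheticCohortSpec(
            n_per_group=(15, 15, 15),
            n_taxa_species=40,
            taxonomy_shape=shape,
            base_logsd=base_logsd,
            planted_ordinal=list(planted),
            seed=seed,
        )
        return generate(spec)

    def test_gate_rule_two_phyla(self):
        """Only children of the FDR-significant phylum are ever tested."""
        rng = np.random.default_rng(0)
        n = 60
        groups = ["HC"] * 20 + ["ASYM_UAS"] * 20 + ["SS_SLE"] * 20
        md = make_metadata(groups, batches=["b1"] * n)
        score = np.repeat([-1.0, 0.0, 1.0], 20)
        # phylum A strongly monotone, phylum B pure noise
        a1 = np.exp(rng.normal(3 + 1.5 * score, 0.3))
        a2 = np.exp(rng.normal(3 + 1.5 * score, 0.3))
        b1 = np.exp(rng.normal(3, 1.0, n))
        b2 = np.exp(rng.normal(3, 1.0, n))
        base = np.exp(rng.normal(7, 0.1, n))
        ct = CountTable(pd.DataFrame(
            np.column_stack([a1, a2, b1, b2, base]).astype(int) + 1,
            index=md.sample_ids, columns=["t1", "t2", "t3", "t4", "t5"]))
        tax = TaxonomyTable(pd.DataFrame(
            [["Bacteria", "A", "Ac", "Ao", "Af", "Ag1", "As1"],
             ["Bacteria", "A", "Ac", "Ao", "Af", "Ag2", "As2"],
             ["Bacteria", "B", "Bc", "Bo", "Bf", "Bg1", "Bs1"],
             ["Bacteria", "B", "Bc", "Bo", "Bf", "Bg2", "Bs2"],
             ["Bacteria", "C", "Cc", "Co", "Cf", "Cg", "Cs"]],
            index=["t1", "t2", "t3", "t4", "t5"], columns=list(RANKS)))
        # stringent alpha: only the strongly monotone phylum A clears its
        # gate (closure induces mild signal in the others, as it must)
        res = tsd(ct, tax, md, alpha=1e-8)
        phyla = res[res["level"] == "phylum"].set_index("name")
        assert set(phyla.index) == {"A", "B", "C"}
        assert phyla.loc["A", "gate_open"]
        assert not phyla.loc["B", "gate_open"]
        deeper = res[res["level"] != "phylum"]
        assert len(deeper) > 0
        # every deeper node descends from an open phylum, never from B
        open_paths = set(res.index[(res["level"] == "phylum") & res["gate_open"]])
        for _, row in res[res["level"] == "class"].iterrows():
            assert row["parent_id"] in open_paths

    def test_never_more_hypotheses_than_flat(self):
        ct, tax, md, _, _ = self._cohort(seed=3, planted=[("G003", 1.5, 1)])
        res = tsd(ct, tax, md)
        flat_total = sum(
            aggregate_to_level(ct, tax, lv).shape[1]
            for lv in RANKS[1:]
        )
        assert len(res) <= flat_total

    def test_signal_genus_recovered_through_gates(self):
        # small phyla and even base abundances so the planted genus carries
        # weight within its own lineage and the signal survives every gate
        hits = 0
        for seed in range(10):
            ct, tax, md, _, truth = self._cohort(seed=seed, base_logsd=0.6,
                                                 small_phyla=True,
                                                 planted=[("G001", 3.0, 1)])
            res = tsd(ct, tax, md, alpha=0.05)
            gen = res[(res["level"] == "genus") & res["gate_open"]]
            hits += "G001" in set(gen["name"])
        assert hits >= 8

    def test_global_null_rarely_reaches_species(self):
        n_discover = 0
        for seed in range(40):
            ct, tax, md, _, _ = self._cohort(seed=100 + seed)
            res = tsd(ct, tax, md, alpha=0.05)
            sp = res[(res["level"] == "species") & res["gate_open"]]
            n_discover += len(sp) > 0
        # expected fraction <= alpha under the global null
        assert n_discover / 40 <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 40)


class TestSummarizeLevel:
    def test_table_layout_and_recovery(self, paper_cohort):
        ct, tax, md, tree, truth = paper_cohort
        tab = summarize_level(ct, tax, md, "genus", alpha=0.05)
        expected_cols = [
            "family", "HC_mean", "HC_sd", "ASYM_UAS_mean", "ASYM_UAS_sd",
            "SS_SLE_mean", "SS_SLE_sd", "p_ordinal3", "p_fdr_ordinal3",
            "direction", "p_hc_vs_antiro", "p_discrete3", "p_fdr_discrete3",
        ]
        assert list(tab.columns) == expected_cols
        planted = {g: s for g, _, s in truth.planted_ordinal}
        found = planted.keys() & set(tab.index)
        assert len(found) >= 10  # most of the 13 planted genera
        for g in found:
            assert np.sign(tab.loc[g, "direction"]) == planted[g]

    def test_no_planted_effects_no_discoveries(self):
        spec = SyntheticCohortSpec(
            n_per_group=(15, 15, 15), n_taxa_species=40,
            taxonomy_shape={"phylum": 3, "class": 5, "order": 8, "family": 15,
                            "genus": 30},
            seed=42,
        )
        ct, tax, md, _, _ = generate(spec)
        tab = summarize_level(ct, tax, md, "genus", alpha=0.05)
        assert len(tab) <= 2
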
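"""Curveball randomization, rank-sum machinery and the permutation pipeline."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import comb

from apobecsig.enrichment import (RankSumScorer, bh_fdr, build_gene_matrix,
                                  curveball_randomize, fisher_exact,
                                  gene_enrichment_pipeline, logistic_or,
                                  permutation_corrected_p, rank_sum_p,
                                  site_enrichment)
from apobecsig.io_formats import MutationRecord


class TestBuildGeneMatrix:
    def _mut(self, sample, gene):
        return MutationRecord(sample, sample, "chr1", 10, "C", "T", gene=gene)

    def test_frequency_floor_and_sample_filter(self):
        cohort = [f"S{i}" for i in range(200)]
        muts = [self._mut("S0", "RARE")]
        muts += [self._mut(f"S{i}", "COMMON") for i in range(10)]
        mat = build_gene_matrix(muts, ["RARE", "COMMON"], cohort)
        assert list(mat.index) == ["COMMON"]  # 0.5% < 1% floor
        assert list(mat.columns) == [f"S{i}" for i in range(10)]

    def test_binary_despite_repeated_mutations(self):
        muts = [self._mut("S0", "G"), self._mut("S0", "G")]
        mat = build_gene_matrix(muts, ["G"], ["S0", "S1"], min_gene_freq=0.0)
        assert mat.loc["G", "S0"] == 1

    def test_oncogenic_only_filter(self):
        m1 = self._mut("S0", "G")
        m1.oncogenic = True
        m2 = self._mut("S1", "G")
        m2.oncogenic = False
        mat = build_gene_matrix([m1, m2], ["G"], ["S0", "S1"],
                                min_gene_freq=0.0, oncogenic_only=True)
        assert list(mat.columns) == ["S0"]


class TestCurveball:
    def test_2x2_stays_in_margin_class(self):
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(200):
            out = curveball_randomize([[1, 0], [0, 1]], rng=rng)
            seen.add(tuple(out.flatten().tolist()))
        assert seen <= {(1, 0, 0, 1), (0, 1, 1, 0)}
        assert len(seen) == 2  # both reachable

    def test_all_ones_unchanged_and_zero_row_stays_zero(self):
        rng = np.random.default_rng(1)
        ones = np.ones((4, 5), dtype=int)
        assert (curveball_randomize(ones, rng=rng) == ones).all()
        m = np.array([[0, 0, 0], [1, 0, 1], [1, 1, 0]])
        out = curveball_randomize(m, rng=rng)
        assert (out[0] == 0).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            curveball_randomize([[0, 2], [1, 0]])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(2, 30), st.integers(2, 40), st.integers(0, 10**6))
    def test_margins_always_preserved(self, r, c, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((r, c)) < 0.3).astype(int)
        out = curveball_randomize(m, rng=rng)
        assert (out.sum(axis=1) == m.sum(axis=1)).all()
        assert (out.sum(axis=0) == m.sum(axis=0)).all()

    def test_large_matrix_margins(self):
        rng = np.random.default_rng(3)
        m = (rng.random((200, 500)) < 0.15).astype(int)
        out = curveball_randomize(m, rng=rng)
        assert (out.sum(axis=1) == m.sum(axis=1)).all()
        assert (out.sum(axis=0) == m.sum(axis=0)).all()


class TestRankSum:
    def test_exact_enumeration_example(self):
        # C(4,2)=6 rank splits; only {3,4} has an as-extreme rank sum
        assert rank_sum_p([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1 / 3)

    def test_identical_constants_p_one(self):
        assert rank_sum_p([1.0, 1.0], [1.0, 1.0]) == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (8, 8), (6, 40)])
    def test_exact_matches_scipy(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            sp = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="exact").pvalue
            assert rank_sum_p(x, y) == pytest.approx(float(sp), abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(12, 30), (50, 150)])
    def test_asymptotic_matches_scipy(self, n1, n2):
        rng = np.random.default_rng(n1)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        sp = stats.mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").pvalue
        assert rank_sum_p(x, y) == pytest.approx(float(sp), rel=1e-9)

    def test_exact_and_approx_agree_at_8v8(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=8), rng.normal(size=8)
        exact = rank_sum_p(x, y)
        approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(exact - float(approx)) < 0.02

    def test_scorer_matches_scalar_function(self):
        rng = np.random.default_rng(9)
        expo = rng.random(40)
        scorer = RankSumScorer(expo)
        mask = np.zeros(40, dtype=bool)
        mask[rng.choice(40, 12, replace=False)] = True
        assert scorer.p_for_mask(mask) == pytest.approx(
            rank_sum_p(expo[mask], expo[~mask]))


class TestPermutationP:
    def test_formula_examples(self):
        assert permutation_corrected_p(0.001, [0.5, 0.9]) == 0.0
        assert permutation_corrected_p(1.0, [0.5, 0.9]) == 1.0
        randoms = [0.01, 0.02, 0.05, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9]
        assert permutation_corrected_p(0.05, randoms) == pytest.approx(0.3)

    def test_tie_counts_as_less_equal(self):
        assert permutation_corrected_p(0.05, [0.05, 0.5]) == 0.5

    def test_add_one_variant(self):
        assert permutation_corrected_p(0.001, [0.5] * 9, add_one=True) == \
            pytest.approx(0.1)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=50),
           st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_observed_p(self, randoms, p1, p2):
        lo, hi = sorted((p1, p2))
        assert permutation_corrected_p(lo, randoms) <= \
            permutation_corrected_p(hi, randoms)


class TestFisherAndBh:
    def test_chr13_loh_worked_example(self):
        p, odds = fisher_exact([[3, 3], [0, 10]])
        assert p == pytest.approx(0.0357, abs=5e-4)

    def test_degenerate_and_diagonal_tables(self):
        assert fisher_exact([[1, 1], [1, 1]])[0] == 1.0
        assert fisher_exact([[5, 0], [0, 5]])[0] == pytest.approx(2 / 252)

    def test_matches_bruteforce_hypergeometric_enumeration(self):
        """Two-sided p equals the sum of hypergeometric probabilities of all
        tables (same margins) at most as likely as the observed one."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(4, 31))
            a_ = int(rng.integers(0, n + 1))
            row1 = int(rng.integers(0, n + 1))
            col1 = int(rng.integers(0, n + 1))
            a = min(a_, row1, col1)
            t = np.array([[a, row1 - a], [col1 - a, n - row1 - col1 + a]])
            if (t < 0).any():
                continue
            r1, r2 = t[0].sum(), t[1].sum()
            c1 = t[:, 0].sum()
            total = comb(r1 + r2, c1, exact=True)
            probs = {}
            for k in range(max(0, c1 - r2), min(r1, c1) + 1):
                probs[k] = (comb(r1, k, exact=True)
                            * comb(r2, c1 - k, exact=True)) / total
            p_obs = probs[t[0, 0]]
            brute = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
            assert fisher_exact(t)[0] == pytest.approx(brute, rel=1e-9)

    def test_bh_step_up_formula(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_bh_hand_computed_three_sites(self):
        q = bh_fdr([0.001, 0.04, 0.9])
        assert np.allclose(q, [0.003, 0.06, 0.9])


class TestLogisticOr:
    def test_closed_form_table(self):
        g = np.r_[np.ones(20), np.zeros(80), np.ones(10), np.zeros(90)]
        grp = np.r_[np.ones(100), np.zeros(100)]
        odds, p = logistic_or(g.astype(bool), grp.astype(bool))
        assert odds == pytest.approx(2.25)

    def test_independence_or_one(self):
        g = np.r_[np.ones(10), np.zeros(90), np.ones(10), np.zeros(90)]
        grp = np.r_[np.ones(100), np.zeros(100)]
        odds, p = logistic_or(g.astype(bool), grp.astype(bool))
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_haldane_finite(self):
        g = np.r_[np.ones(5), np.zeros(95), np.zeros(100)]
        grp = np.r_[np.ones(100), np.zeros(100)]
        odds, p = logistic_or(g.astype(bool), grp.astype(bool))
        assert np.isfinite(odds) and odds > 1


class TestSiteEnrichment:
    def test_group_exclusive_site_most_significant(self):
        rng = np.random.default_rng(1)
        n = 200
        grp = np.r_[np.ones(100), np.zeros(100)].astype(bool)
        sites = pd.DataFrame({
            "hot": np.r_[rng.random(100) < 0.10, np.zeros(100)].astype(int),
            "flat": (rng.random(n) < 0.05).astype(int),
        })
        out = site_enrichment(sites, grp)
        assert out.index[0] == "hot"
        assert out.loc["hot", "odds_ratio"] > 1

    def test_equal_frequency_near_null(self):
        grp = np.r_[np.ones(100), np.zeros(100)].astype(bool)
        sites = pd.DataFrame({"s": np.r_[np.ones(10), np.zeros(90),
                                         np.ones(10), np.zeros(90)].astype(int)})
        out = site_enrichment(sites, grp)
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_bh_across_sites_matches_direct(self):
        grp = np.r_[np.ones(50), np.zeros(50)].astype(bool)
        rng = np.random.default_rng(2)
        sites = pd.DataFrame(
            {f"s{i}": (rng.random(100) < 0.2).astype(int) for i in range(3)})
        out = site_enrichment(sites, grp)
        assert np.allclose(np.sort(out["q"]),
                           np.sort(bh_fdr(out["p"].to_numpy())))


class TestPipeline:
    def test_single_gene_q_equals_p(self):
        rng = np.random.default_rng(0)
        expo = pd.Series(rng.random(40), index=[f"S{i}" for i in range(40)])
        row = (rng.random(40) < 0.3).astype(int)
        row[0] = 1
        mat = pd.DataFrame([row], index=["G0"], columns=expo.index)
        res = gene_enrichment_pipeline(mat, expo, n_perm=200, rng=rng)
        assert res.loc["G0", "q"] == pytest.approx(res.loc["G0", "p_observed"])

    def test_injected_association_detected(self):
        """A gene whose mutation probability rises with exposure is flagged
        against margin-matched permutations; null genes are not."""
        from apobecsig.synthetic import simulate_gene_matrix
        rng = np.random.default_rng(5)
        expo = np.r_[np.zeros(150), np.ones(150)]
        rng.shuffle(expo)
        mat, _ = simulate_gene_matrix(expo, rng, n_genes=20,
                                      betas={0: np.log(8.0)})
        mat = mat.loc[mat.sum(axis=1) > 0, mat.sum(axis=0) >= 0]
        expos = pd.Series(expo, index=mat.columns)
        res = gene_enrichment_pipeline(mat, expos, n_perm=300, rng=rng)
        assert res.index[0] == "GENE000"
        assert res["p_permutation"].iloc[0] <= 0.01
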
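"""Gene- and site-level association with APOBEC3 activity.

The central procedure tests, per gene, whether mutated samples have higher
APOBEC3 exposure than wild-type samples (two-sided Wilcoxon rank-sum), and
corrects each observed p against an empirical null built by randomizing the
binary gene x sample mutation matrix while preserving every row and column
margin (the curveball algorithm of Strona et al.).  Margin preservation is
what makes the null fair: hypermutated samples stay hypermutated and long,
frequently hit genes stay frequently hit in every permuted matrix, so the
test asks only whether mutations co-occur with exposure *given* those
margins.  The final p per gene is

    p_perm = #(p_random <= p_observed) / n_permutations

with p_random recomputed per gene on each randomized matrix, and
Benjamini-Hochberg FDR across genes.

Because every permutation preserves the per-gene mutant count and the
exposure ranks never change, the rank-sum statistic of a permuted matrix is
just a dot product of the 0/1 gene row with the fixed rank vector; the
per-gene null p can therefore be read off a precomputed statistic->p map
(exact for small mutant counts without ties, normal approximation with tie
and continuity corrections otherwise).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MutationRecord
from .synthetic import as_rng

EXACT_MAX_N = 8


# ---------------------------------------------------------------------------
# gene x sample matrix construction


def build_gene_matrix(mutations: Sequence[MutationRecord],
                      gene_universe: Sequence[str],
                      cohort_samples: Sequence[str],
                      min_gene_freq: float = 0.01,
                      oncogenic_only: bool = False) -> pd.DataFrame:
    """Binary gene x sample mutation matrix with the cohort filters.

    A cell is 1 when the sample carries at least one qualifying mutation in
    the gene.  Genes mutated in fewer than ``min_gene_freq`` of the cohort
    are dropped first; samples left without any mutation in a retained gene
    are then dropped.
    """
    samples = list(dict.fromkeys(cohort_samples))
    genes = list(dict.fromkeys(gene_universe))
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=np.int8)
    for m in mutations:
        if oncogenic_only and not m.oncogenic:
            continue
        if m.gene in mat.index and m.sample_id in mat.columns:
            mat.loc[m.gene, m.sample_id] = 1
    freq = mat.sum(axis=1) / len(samples)
    mat = mat.loc[freq >= min_gene_freq]
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    return mat


# ---------------------------------------------------------------------------
# curveball randomization


def curveball_randomize(matrix, n_iterations: Optional[int] = None,
                        rng=None) -> np.ndarray:
    """Margin-preserving randomization of a binary matrix.

    Repeatedly picks a random pair of rows and reshuffles the columns where
    exactly one of the two rows has a 1 (a batch of checkerboard trades).
    Every row and column margin of the output equals the input's exactly.
    """
    arr = np.asarray(matrix)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("curveball requires a binary 0/1 matrix")
    arr = arr.astype(np.int8)
    rng = as_rng(rng)
    n_rows, n_cols = arr.shape
    if n_rows < 2:
        return arr.copy()
    if n_iterations is None:
        n_iterations = 5 * min(n_rows, n_cols)
    row_sets = [set(np.nonzero(arr[r])[0].tolist()) for r in range(n_rows)]
    # pre-draw all randomness: row pairs, and floats whose argsort shuffles
    ii = rng.integers(0, n_rows, size=n_iterations)
    jj = rng.integers(0, n_rows - 1, size=n_iterations)
    jj[jj >= ii] += 1
    shuffle_keys = rng.random((n_iterations, n_cols))
    for t in range(n_iterations):
        si, sj = row_sets[ii[t]], row_sets[jj[t]]
        common = si & sj
        only_i = list(si - common)
        only_j = list(sj - common)
        if not only_i or not only_j:
            continue
        pool = only_i + only_j
        order = np.argsort(shuffle_keys[t, :len(pool)])
        row_sets[ii[t]] = common | {pool[k] for k in order[:len(only_i)]}
        row_sets[jj[t]] = common | {pool[k] for k in order[len(only_i):]}
    out = np.zeros_like(arr)
    for r, s in enumerate(row_sets):
        if s:
            out[r, list(s)] = 1
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _exact_w_counts(k: int, n_total: int) -> np.ndarray:
    """Number of k-subsets of ranks {1..n_total} with each possible sum.

    Index s of the returned array counts subsets summing to s.
    """
    max_sum = sum(range(n_total - k + 1, n_total + 1))
    f = np.zeros((k + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n_total + 1):
        for kk in range(min(k, i), 0, -1):
            f[kk, i:] += f[kk - 1, :-i or None]
    return f[k]


class RankSumScorer:
    """Precomputed rank-sum p machinery over a fixed exposure vector.

    Maps a mutant-group rank sum W (for a given mutant count n1) to the
    two-sided p-value.  Uses the exact permutation null when the smaller
    group has at most ``EXACT_MAX_N`` members and the exposures are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """

    def __init__(self, exposures: Sequence[float]):
        self.values = np.asarray(exposures, dtype=float)
        self.ranks = stats.rankdata(self.values)
        self.n = len(self.values)
        self.tie_term = _tie_term(self.ranks)
        self.has_ties = self.tie_term > 0
        self._exact_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _exact_dists(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k not in self._exact_cache:
            counts = _exact_w_counts(k, self.n)
            total = counts.sum()
            cdf = np.cumsum(counts) / total
            sf = np.cumsum(counts[::-1])[::-1] / total
            self._exact_cache[k] = (cdf, sf)
        return self._exact_cache[k]

    def p_value(self, w, n1) -> np.ndarray:
        """Two-sided p for mutant rank-sum(s) ``w`` with mutant count ``n1``."""
        w = np.atleast_1d(np.asarray(w, dtype=float))
        n1 = np.atleast_1d(np.asarray(n1, dtype=int))
        n1 = np.broadcast_to(n1, w.shape).copy()
        n2 = self.n - n1
        out = np.ones_like(w, dtype=float)
        small = np.minimum(n1, n2)
        exact = (small <= EXACT_MAX_N) & (small > 0)
        if self.has_ties:
            exact[:] = False
        t_all = self.n * (self.n + 1) / 2.0

        for idx in np.nonzero(exact)[0]:
            k1, k2 = int(n1[idx]), int(n2[idx])
            if k1 <= k2:
                k, ws = k1, w[idx]
            else:  # mirror onto the smaller (wild-type) side
                k, ws = k2, t_all - w[idx]
            cdf, sf = self._exact_dists(k)
            s = int(round(ws))
            s = min(max(s, 0), len(cdf) - 1)
            out[idx] = min(1.0, 2.0 * min(cdf[s], sf[s]))

        approx = ~exact & (small > 0)
        if approx.any():
            a1 = n1[approx].astype(float)
            a2 = n2[approx].astype(float)
            mu = a1 * (self.n + 1) / 2.0
            var = (a1 * a2 / 12.0) * (
                (self.n + 1) - self.tie_term / (self.n * (self.n - 1)))
            sd = np.sqrt(var)
            diff = np.abs(w[approx] - mu)
            z = np.where(sd > 0, np.maximum(diff - 0.5, 0.0) / np.where(
                sd > 0, sd, 1.0), 0.0)
            out[approx] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
        return out

    def p_for_mask(self, mutant_mask: np.ndarray) -> float:
        mask = np.asarray(mutant_mask, dtype=bool)
        w = float(self.ranks[mask].sum())
        return float(self.p_value(w, int(mask.sum()))[0])


def rank_sum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p comparing two samples.

    Exact permutation distribution when the smaller sample has at most 8
    observations and there are no ties; otherwise the tie-corrected,
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    scorer = RankSumScorer(np.concatenate([x, y]))
    mask = np.zeros(len(x) + len(y), dtype=bool)
    mask[:len(x)] = True
    return scorer.p_for_mask(mask)


# ---------------------------------------------------------------------------
# permutation correction and FDR


def permutation_corrected_p(p_observed: float,
                            p_randoms: Sequence[float],
                            add_one: bool = False) -> float:
    """Empirical permutation p: #(p_random <= p_observed) / N.

    Ties (p_random exactly equal to p_observed) count as <=.  With
    ``add_one`` the positively-biased (k+1)/(N+1) estimator is used instead.
    """
    p_randoms = np.asarray(p_randoms, dtype=float)
    n = len(p_randoms)
    if n == 0:
        raise ValueError("no permutation p-values supplied")
    k = int(np.sum(p_randoms <= p_observed + 1e-12))
    if add_one:
        return (k + 1) / (n + 1)
    return k / n


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped to 1, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (p, sample odds ratio).  The p-value is the exact hypergeometric
    sum over tables at most as probable as the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    res = stats.fisher_exact(t, alternative="two-sided")
    a, b = float(t[0, 0]), float(t[0, 1])
    c, d = float(t[1, 0]), float(t[1, 1])
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return float(res.pvalue), odds


def logistic_or(gene_indicator: Sequence[int],
                group_indicator: Sequence[int]) -> tuple[float, float]:
    """Univariate logistic odds ratio of mutation on group status.

    Equivalent to the 2x2 sample odds ratio; zero cells are handled by the
    Haldane-Anscombe correction (+0.5 to every cell) before both the OR and
    the Wald p.
    """
    g = np.asarray(gene_indicator, dtype=bool)
    grp = np.asarray(group_indicator, dtype=bool)
    if g.shape != grp.shape:
        raise ValueError("indicator lengths differ")
    a = float(np.sum(g & grp))      # mutated, in group
    b = float(np.sum(g & ~grp))     # mutated, out of group
    c = float(np.sum(~g & grp))
    d = float(np.sum(~g & ~grp))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(odds) / se
    p = float(2 * stats.norm.sf(abs(z)))
    return float(odds), p


# ---------------------------------------------------------------------------
# pipelines


def gene_enrichment_pipeline(matrix: pd.DataFrame,
                             exposures: pd.Series,
                             n_perm: int = 10_000,
                             n_curveball_iter: Optional[int] = None,
                             rng=None,
                             dominant: Optional[pd.Series] = None,
                             add_one: bool = False,
                             bh_on: str = "observed") -> pd.DataFrame:
    """Per-gene APOBEC3 enrichment with margin-preserving permutation nulls.

    Parameters
    ----------
    matrix : binary gene x sample DataFrame (output of build_gene_matrix).
    exposures : per-sample APOBEC3 exposure, indexed by sample id.
    n_perm : number of curveball-randomized matrices (each restarted from
        the observed matrix).
    dominant : optional per-sample APOBEC3-dominant flag; when given, an
        odds ratio of mutation on dominance (Haldane-corrected) is reported.
    bh_on : apply BH FDR to "observed" p-values (default) or "permutation".

    Returns a per-gene table: mutant count and fraction, p_observed,
    p_permutation, q, and optionally odds_ratio / log2_or.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse permutation p granularity")
    if bh_on not in ("observed", "permutation"):
        raise ValueError("bh_on must be 'observed' or 'permutation'")
    rng = as_rng(rng)
    expo = exposures.loc[matrix.columns].to_numpy(dtype=float)
    arr = matrix.to_numpy()
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("gene matrix must be binary")
    arr = arr.astype(np.int8)
    n_genes, n_samples = arr.shape
    n1 = arr.sum(axis=1)
    degenerate = (n1 == 0) | (n1 == n_samples)
    if degenerate.any():
        warnings.warn(f"dropping {int(degenerate.sum())} genes with empty "
                      "mutant or wild-type groups (rank-sum undefined)")
        matrix = matrix.loc[~degenerate]
        arr = arr[~degenerate]
        n1 = n1[~degenerate]
        n_genes = arr.shape[0]
        if n_genes == 0:
            raise ValueError("no testable genes left")
    scorer = RankSumScorer(expo)
    w_obs = arr.astype(float) @ scorer.ranks
    p_obs = scorer.p_value(w_obs, n1)

    exceed = np.zeros(n_genes, dtype=np.int64)
    for _ in range(n_perm):
        perm = curveball_randomize(arr, n_iterations=n_curveball_iter, rng=rng)
        w_rand = perm.astype(float) @ scorer.ranks
        p_rand = scorer.p_value(w_rand, n1)  # margins: n1 unchanged
        exceed += p_rand <= p_obs + 1e-12
    if add_one:
        p_perm = (exceed + 1) / (n_perm + 1)
    else:
        p_perm = exceed / n_perm

    q = bh_fdr(p_obs if bh_on == "observed" else p_perm)
    result = pd.DataFrame({
        "gene": matrix.index,
        "n_mutant": n1,
        "mutated_fraction": n1 / n_samples,
        "p_observed": p_obs,
        "p_permutation": p_perm,
        "q": q,
    }).set_index("gene")
    if dominant is not None:
        dom = dominant.loc[matrix.columns].to_numpy(dtype=bool)
        ors, wald = zip(*(logistic_or(arr[g], dom) for g in range(n_genes)))
        result["odds_ratio"] = ors
        result["log2_or"] = np.log2(ors)
        result["or_wald_p"] = wald
    return result.sort_values("p_permutation")


def site_enrichment(site_matrix: pd.DataFrame,
                    group: Sequence[bool],
                    method: str = "fisher") -> pd.DataFrame:
    """Per-site enrichment of mutations in a sample group, BH-corrected.

    ``site_matrix`` is samples x sites binary (1 = sample mutated at the
    site); ``group`` flags the samples in the enriched-candidate group.
    """
    grp = np.asarray(group, dtype=bool)
    if len(grp) != len(site_matrix):
        raise ValueError("group length must match sample count")
    rows = []
    for site in site_matrix.columns:
        mut = site_matrix[site].to_numpy(dtype=bool)
        a = int(np.sum(mut & grp))
        b = int(np.sum(mut & ~grp))
        c = int(np.sum(~mut & grp))
        d = int(np.sum(~mut & ~grp))
        if method == "fisher":
            p, odds = fisher_exact([[a, b], [c, d]])
            if not np.isfinite(odds):
                odds, _ = logistic_or(mut, grp)
        elif method == "logistic":
            odds, p = logistic_or(mut, grp)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"site": site, "n_group": a, "n_other": b,
                     "odds_ratio": odds, "p": p})
    out = pd.DataFrame(rows).set_index("site")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values("p")
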
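"""The synthetic-cohort generators: determinism and statistical structure."""

import numpy as np
import pandas as pd
import pytest

from apobecsig.catalog import (APOBEC3_CHANNEL_MASK, CHANNEL_LABELS,
                               build_catalog)
from apobecsig.signatures import cosine_similarity
from apobecsig.synthetic import (CohortConfig, SiteIndex, draw_burdens,
                                 make_reference, simulate_cn_segments,
                                 simulate_gene_matrix,
                                 simulate_paired_cohort,
                                 simulate_sample_mutations, simulate_survival,
                                 synthetic_signature_matrix,
                                 toy_signature_matrix)


class TestMakeReference:
    def test_genes_disjoint_and_panel_subsets(self):
        ref, genes, fp = make_reference(genome_length=100_000, n_genes=20,
                                        gene_length=2_000, seed=0)
        assert len(genes) == 20
        ends = genes.sort_values("start")
        assert (ends["start"].to_numpy()[1:] >=
                ends["end"].to_numpy()[:-1]).all()
        assert fp.total_bases == 40_000  # panel_fraction 1.0 = gene footprint

    def test_partial_panel_fraction(self):
        _, genes, fp = make_reference(genome_length=100_000, n_genes=20,
                                      gene_length=2_000, panel_fraction=0.25,
                                      seed=0)
        assert fp.total_bases == 10_000

    def test_same_seed_identical_fasta(self):
        r1, _, _ = make_reference(genome_length=20_000, n_genes=4,
                                  gene_length=1_000, seed=7)
        r2, _, _ = make_reference(genome_length=20_000, n_genes=4,
                                  gene_length=1_000, seed=7)
        assert r1["chr1"] == r2["chr1"]

    def test_infeasible_packing_errors(self):
        with pytest.raises(ValueError):
            make_reference(genome_length=1_000, n_genes=10, gene_length=200)


class TestSimulateSampleMutations:
    def test_pure_tpc_signature_forces_contexts(self, site_index):
        sigs = pd.DataFrame(
            {"PURE": np.where([lab.startswith("T[C>T]")
                               for lab in CHANNEL_LABELS], 0.25, 0.0)},
            index=list(CHANNEL_LABELS))
        muts = simulate_sample_mutations([1.0], 50, sigs, site_index, 3)
        assert len(muts) == 50
        for m in muts:
            assert (m.ref, m.alt) in {("C", "T"), ("G", "A")}

    def test_zero_mutations_empty(self, site_index, signatures):
        e = np.zeros(signatures.shape[1])
        e[0] = 1.0
        assert simulate_sample_mutations(e, 0, signatures, site_index, 0) == []

    def test_burden_conserved_and_positions_unique(self, site_index,
                                                   signatures):
        e = np.full(signatures.shape[1], 1 / signatures.shape[1])
        muts = simulate_sample_mutations(e, 500, signatures, site_index, 5)
        assert len(muts) == 500
        assert len({(m.chrom, m.pos) for m in muts}) == 500

    def test_empirical_spectrum_matches_mixture(self, small_reference,
                                                site_index, signatures):
        """2,000 draws from a 0.6/0.4 mixture: empirical 96-channel
        frequencies have cosine similarity > 0.98 to the mixture."""
        reference, _, _ = small_reference
        e = np.zeros(signatures.shape[1])
        e[list(signatures.columns).index("SBS2")] = 0.6
        e[list(signatures.columns).index("SBS5")] = 0.4
        muts = simulate_sample_mutations(e, 2000, signatures, site_index, 11)
        cat = build_catalog(muts, reference)
        mixture = signatures.to_numpy() @ e
        assert cosine_similarity(cat.row("S1"), mixture) > 0.98

    def test_determinism(self, site_index, signatures):
        e = np.full(signatures.shape[1], 1 / signatures.shape[1])
        a = simulate_sample_mutations(e, 100, signatures, site_index, 42)
        b = simulate_sample_mutations(e, 100, signatures, site_index, 42)
        assert [(m.chrom, m.pos, m.ref, m.alt) for m in a] == \
            [(m.chrom, m.pos, m.ref, m.alt) for m in b]

    def test_absent_context_named_in_error(self, signatures):
        tiny = SiteIndex({"chr1": "AAAAAAA"})  # no C/G sites at all
        e = np.zeros(signatures.shape[1])
        e[1] = 1.0
        with pytest.raises(ValueError, match="context"):
            simulate_sample_mutations(e, 10, signatures, tiny, 0)


class TestGeneMatrix:
    def test_null_matrix_independent_of_exposure(self):
        rng_expo = np.random.default_rng(0).random(400)
        mat, truth = simulate_gene_matrix(rng_expo, seed=1, n_genes=30)
        assert set(np.unique(mat.to_numpy())) <= {0, 1}
        assert (truth["beta"] == 0).all()
        # overall mutation rate near the 10% baseline
        assert abs(mat.to_numpy().mean() - 0.10) < 0.02

    def test_saturating_effect(self):
        expo = np.r_[np.zeros(50), np.ones(50)]
        mat, _ = simulate_gene_matrix(expo, seed=2, n_genes=5,
                                      betas={0: 10.0})
        high = mat.iloc[0, 50:].mean()
        assert high > 0.95

    def test_logistic_or_recovered_across_exposure_halves(self):
        """alpha=logit(0.1), beta=log(3) on a binary exposure: the empirical
        odds ratio over many replicates matches the generating effect."""
        expo = np.r_[np.zeros(100), np.ones(100)]
        ors = []
        rng = np.random.default_rng(3)
        for _ in range(200):
            mat, _ = simulate_gene_matrix(expo, rng, n_genes=1,
                                          betas={0: np.log(3.0)})
            row = mat.to_numpy()[0]
            a, b = row[100:].sum() + 0.5, (1 - row[100:]).sum() + 0.5
            c, d = row[:100].sum() + 0.5, (1 - row[:100]).sum() + 0.5
            ors.append((a * d) / (b * c))
        assert np.median(ors) == pytest.approx(3.0, rel=0.25)


class TestPairedCohort:
    def test_shared_fraction_one_means_late_contains_early(self, site_index):
        sim = simulate_paired_cohort(site_index, 5, n_patients=3,
                                     n_early=20, shared_fraction=1.0,
                                     n_acquired=0)
        for d in sim["patients"].values():
            early_sites = {m.site for m in d["early"]}
            late_sites = {m.site for m in d["late"]}
            assert late_sites == early_sites

    def test_shared_fraction_zero_no_common_sites(self, site_index):
        sim = simulate_paired_cohort(site_index, 5, n_patients=3,
                                     n_early=20, shared_fraction=0.0,
                                     n_acquired=10)
        for d in sim["patients"].values():
            early_sites = {m.site[:2] for m in d["early"]}
            late_sites = {m.site[:2] for m in d["late"]}
            assert not early_sites & late_sites

    def test_truth_labels_partition_late_mutations(self, site_index):
        sim = simulate_paired_cohort(site_index, 8, n_patients=5)
        truth = sim["truth"]
        for pid, d in sim["patients"].items():
            t = truth[truth.patient_id == pid]
            assert len(t) == len(d["late"])
            assert set(t["truth"]) <= {"shared", "acquired"}


class TestSurvivalAndCn:
    def test_infinite_censor_window_all_events(self):
        df = simulate_survival({"A": 200}, {"A": 0.1}, np.inf, 0)
        assert (df["event"] == 1).all()

    def test_group_rates_reflected_in_means(self):
        df = simulate_survival({"A": 2000, "B": 2000},
                               {"A": 1 / 5.0, "B": 1 / 20.0}, np.inf, 1)
        mean_a = df[df.group == "A"].time_months.mean()
        mean_b = df[df.group == "B"].time_months.mean()
        assert mean_a == pytest.approx(5.0, rel=0.1)
        assert mean_b == pytest.approx(20.0, rel=0.1)

    @pytest.mark.parametrize("fraction,expected_flag",
                             [(1.0, True), (0.0, False), (0.5, False)])
    def test_cn_doubled_fraction_forced(self, fraction, expected_flag):
        from apobecsig.genome_metrics import wgd_call
        segs = simulate_cn_segments(wgd=False, seed=4,
                                    doubled_fraction=fraction)
        flag, frac = wgd_call(segs)
        assert frac == pytest.approx(fraction)
        assert flag is expected_flag


def test_burdens_match_negative_binomial_moments():
    rng = np.random.default_rng(0)
    x = draw_burdens(20_000, mean=200.0, dispersion=5.0, rng=rng)
    assert x.mean() == pytest.approx(200.0, rel=0.05)
    assert x.var() == pytest.approx(200.0 + 200.0**2 / 5.0, rel=0.1)


def test_toy_signatures_orthogonal():
    toy = toy_signature_matrix(("A", "B", "C"))
    gram = toy.to_numpy().T @ toy.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.allclose(off, 0)


def test_config_validation():
    with pytest.raises(ValueError):
        CohortConfig(shared_fraction=1.5)
    with pytest.raises(ValueError):
        CohortConfig(dirichlet_concentration=0)
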
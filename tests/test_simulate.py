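"""Synthetic-data generators: structure, cancellation maps, seedlings,
reference panels."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epigwa as eg
from epigwa.simulate import PopulationSpec


def hudson_fst(calls, labels):
    """Two-population Hudson Fst from haploid-equivalent calls.

    Independent oracle: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    den = p1(1-p2) + p2(1-p1), ratio of sums over SNPs.
    """
    g = (calls == 1).astype(float)
    p1 = g[labels == 0].mean(axis=0)
    p2 = g[labels == 1].mean(axis=0)
    n1 = (labels == 0).sum()
    n2 = (labels == 1).sum()
    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return num[ok].sum() / den[ok].sum()


class TestSimulatePanel:
    def test_same_seed_identical(self):
        spec = PopulationSpec(n_accessions=30, n_snps=50, seed=9)
        a, la = eg.simulate_panel(spec)
        b, lb = eg.simulate_panel(spec)
        assert np.array_equal(a.calls, b.calls)
        assert np.array_equal(la, lb)

    def test_low_divergence_tracks_ancestral_frequency(self):
        # fst -> 0: realized frequencies concentrate on the ancestral draw
        spec = PopulationSpec(n_accessions=500, n_snps=500, n_subpops=1,
                              fst=0.001, ancestral_maf_range=(0.1, 0.4),
                              seed=2)
        gm, _ = eg.simulate_panel(spec)
        rng = np.random.default_rng(2)
        ancestral = rng.uniform(0.1, 0.4, size=500)  # same stream position
        freq = (gm.calls == 1).mean(axis=0)
        # coding re-normalization may flip ties; compare folded frequency
        dev = np.abs(np.minimum(freq, 1 - freq)
                     - np.minimum(ancestral, 1 - ancestral))
        assert dev.mean() < 0.05

    def test_divergence_matches_hudson_fst_oracle(self):
        ests = []
        for seed in range(10):
            spec = PopulationSpec(n_accessions=200, n_snps=400, n_subpops=2,
                                  fst=0.3, seed=seed)
            gm, labels = eg.simulate_panel(spec)
            ests.append(hudson_fst(gm.calls, labels))
        assert abs(np.mean(ests) - 0.3) < 0.1

    def test_inbred_coding_only(self, small_panel):
        gm, _ = small_panel
        assert set(np.unique(gm.calls)) <= {-1, 1}
        assert (gm.maf() <= 0.5 + 1e-12).all()

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError, match="fst"):
            PopulationSpec(fst=1.5)


class TestCancellationMap:
    def test_hand_worked_quarter_frequency(self):
        mp = eg.make_cancellation_map(5.0, 1.0, 0.25)
        assert np.allclose(mp.means, [[5.0, 4.0], [4.0, 7.0]])

    def test_half_frequency_symmetry(self):
        mp = eg.make_cancellation_map(5.0, 1.0, 0.5)
        assert np.allclose(mp.means, [[5.0, 4.0], [4.0, 5.0]])

    def test_zero_deficit_rejected(self):
        with pytest.raises(ValueError):
            eg.make_cancellation_map(5.0, 0.0, 0.25)
        with pytest.raises(ValueError):
            eg.make_cancellation_map(5.0, 1.0, 0.0)

    @given(baseline=st.floats(-10, 10), d=st.floats(0.01, 5),
           q=st.floats(0.05, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_zero_marginal_identity(self, baseline, d, q):
        # (1-q)(g(+1,-1)-g(-1,-1)) + q(g(+1,+1)-g(-1,+1)) = 0, both loci
        g = eg.make_cancellation_map(baseline, d, q).means
        for axis in (0, 1):
            m = g if axis == 0 else g.T
            lhs = (1 - q) * (m[1, 0] - m[0, 0]) + q * (m[1, 1] - m[0, 1])
            assert abs(lhs) < 1e-9 * max(1.0, abs(baseline) + d / q)

    @given(d=st.floats(0.01, 5), q=st.floats(0.05, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_decomposition_reports_zero_additive(self, d, q):
        mp = eg.make_cancellation_map(5.0, d, q)
        dec = eg.decompose_map(mp.means, eg.independent_freqs(q, q))
        assert dec.v_a == pytest.approx(0.0, abs=1e-10 * max(1.0, dec.v_g))


class TestPlantEpistaticPair:
    def test_noiseless_takes_four_values(self, small_panel):
        gm, _ = small_panel
        mp = eg.make_cancellation_map(5.0, 1.0, 0.3)
        _, y, truth = eg.plant_epistatic_pair(gm, mp, 0.0, seed=1,
                                              synthesize=True)
        assert len(np.unique(np.round(y, 9))) <= 4
        assert truth.realized_r2 == pytest.approx(1.0)

    def test_same_seed_identical(self, small_panel):
        gm, _ = small_panel
        mp = eg.make_cancellation_map(5.0, 1.0, 0.3)
        _, y1, _ = eg.plant_epistatic_pair(gm, mp, 0.5, seed=4,
                                           synthesize=True)
        _, y2, _ = eg.plant_epistatic_pair(gm, mp, 0.5, seed=4,
                                           synthesize=True)
        assert np.array_equal(y1, y2)

    def test_no_matching_pair_reports_closest(self):
        gm, _ = eg.simulate_panel(PopulationSpec(
            n_accessions=50, n_snps=20, ancestral_maf_range=(0.45, 0.5),
            fst=0.05, seed=8))
        mp = eg.make_cancellation_map(5.0, 1.0, 0.05)
        with pytest.raises(ValueError, match="closest"):
            eg.plant_epistatic_pair(gm, mp, 0.5, freq_tol=0.01)

    def test_cancellation_hides_single_locus_signal(self, small_panel):
        # pair R2 ~ 0.15, yet each planted SNP alone shows no more
        # association than a null SNP: the sample R2 of an uncorrelated
        # regressor has expectation 1/(n-1), which is the floor any
        # perfectly cancelled locus must sit on
        gm, _ = small_panel
        n = gm.n
        mp = eg.make_cancellation_map(5.0, 1.0, 0.25)
        sd = eg.residual_sd_for_r2(mp, 0.15)
        r2_single = []
        for seed in range(20):
            gm2, y, truth = eg.plant_epistatic_pair(gm, mp, sd, seed=seed,
                                                    synthesize=True)
            for j in (truth.snp_a, truth.snp_b):
                x = gm2.calls[:, j].astype(float)
                r2_single.append(np.corrcoef(x, y)[0, 1] ** 2)
        null_floor = 1.0 / (n - 1)
        mcse = np.std(r2_single) / np.sqrt(len(r2_single))
        assert np.mean(r2_single) < null_floor + 3 * mcse
        # an order of magnitude below the pair's own signal
        assert np.mean(r2_single) < 0.02


class TestSimulateSeedlings:
    def test_degenerate_noise_returns_accession_means(self):
        means = eg.simulate_accession_means(n=9, seed=0)
        df = eg.simulate_seedlings(means, n_sets=2, n_replicates=2,
                                   n_per_replicate=3, set_shift_sd=0.0,
                                   replicate_shift_sd=0.0, seedling_sd=0.0,
                                   short_hypocotyl_rate=0.0, seed=1)
        for acc, sub in df.groupby("accession_id"):
            assert np.allclose(sub["root_length"], means[acc])

    def test_short_hypocotyl_rate_binomial(self):
        means = eg.simulate_accession_means(n=21, seed=0)
        df = eg.simulate_seedlings(means, n_sets=2, n_replicates=2,
                                   n_per_replicate=25,
                                   short_hypocotyl_rate=0.05, seed=3)
        n = len(df)
        n_short = (df["hypocotyl_length"] < 5.0).sum()
        se = np.sqrt(n * 0.05 * 0.95)
        assert abs(n_short - 0.05 * n) < 4 * se

    def test_missing_control_rejected(self):
        means = eg.simulate_accession_means(n=5, seed=0).drop("Col-0")
        with pytest.raises(ValueError, match="control"):
            eg.simulate_seedlings(means, seed=0)

    def test_prep_recovers_accession_ranking(self):
        means = eg.simulate_accession_means(n=24, sd=1.0, seed=5)
        df = eg.simulate_seedlings(means, n_sets=2, n_replicates=3,
                                   n_per_replicate=25, set_shift_sd=1.0,
                                   replicate_shift_sd=0.5, seedling_sd=0.5,
                                   seed=6)
        table, _ = eg.standardize(df, control_id="Col-0")
        est = table.set_index("accession_id")["mean"].reindex(means.index)
        from scipy.stats import spearmanr
        assert spearmanr(est, means).statistic > 0.95


class TestReferencePanel:
    def test_same_seed_identical(self):
        a, _ = eg.simulate_reference_panel(n_accessions=60, n_variants=40,
                                           seed=2)
        b, _ = eg.simulate_reference_panel(n_accessions=60, n_variants=40,
                                           seed=2)
        assert np.array_equal(a.calls, b.calls)

    def test_null_mean_r2_matches_permutation_expectation(self):
        # independent variants: E[r^2] with any fixed vector = 1/(n-1)
        panel, _ = eg.simulate_reference_panel(n_accessions=728,
                                               n_variants=3000, seed=4)
        ind = np.zeros(728)
        ind[:40] = 1.0
        x = ind - ind.mean()
        D = panel.calls.astype(float)
        D = D - D.mean(axis=0)
        dn = np.sqrt((D ** 2).sum(axis=0))
        r = (x @ D) / (np.sqrt((x ** 2).sum()) * dn)
        assert np.mean(r ** 2) == pytest.approx(1 / 727, rel=0.15)

    def test_planted_r2_one_is_exact_copy(self):
        pseudo = np.zeros(100, dtype=int)
        pseudo[:20] = 1
        panel, j = eg.simulate_reference_panel(n_accessions=100,
                                               n_variants=50, pseudo=pseudo,
                                               planted_r2=1.0, seed=5)
        col = (panel.calls[:, j] == 1).astype(int)
        r2 = np.corrcoef(col, pseudo)[0, 1] ** 2
        assert r2 == pytest.approx(1.0)

    def test_planted_r2_within_band(self):
        pseudo = np.zeros(200, dtype=int)
        pseudo[:30] = 1
        panel, j = eg.simulate_reference_panel(n_accessions=200,
                                               n_variants=50, pseudo=pseudo,
                                               planted_r2=0.85, seed=6)
        col = (panel.calls[:, j] == 1).astype(int)
        r2 = np.corrcoef(col, pseudo)[0, 1] ** 2
        assert 0.8 <= r2 <= 0.9

    def test_infeasible_plant_rejected(self):
        with pytest.raises(ValueError):
            eg.simulate_reference_panel(n_accessions=50, n_variants=10,
                                        pseudo=np.zeros(50, dtype=int),
                                        planted_r2=0.9, seed=0)
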
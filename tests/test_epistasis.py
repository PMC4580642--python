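"""Two-locus scan: filters, OLS oracle, thresholds, collapsing, R2."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import epigwa as eg
from epigwa.datatypes import ScanConfig
from epigwa.epistasis import EpistasisScan, _ld_r2
from epigwa.simulate import PopulationSpec

from conftest import make_matrix


class TestFilterSnps:
    def test_strict_inequality_at_boundary(self):
        # 4 accessions: one +1 of 4 -> maf 0.25 excluded; 2 of 4 at tie
        calls = np.array([[1, 1], [-1, 1], [-1, -1], [-1, -1]])
        gm = make_matrix(calls)
        kept = eg.filter_snps(gm, 0.25)
        assert kept.snp_ids == [gm.snps[1].id]

    def test_count_matches_brute_force(self, small_panel):
        gm, _ = small_panel
        kept = eg.filter_snps(gm, 0.25)
        brute = sum(1 for j in range(gm.m)
                    if (gm.calls[:, j] == 1).mean() > 0.25)
        assert kept.m == brute

    def test_empty_result_rejected(self):
        calls = np.array([[1], [-1], [-1], [-1]])
        with pytest.raises(ValueError, match="no SNPs"):
            eg.filter_snps(make_matrix(calls), 0.45)


class TestPairScan:
    def test_minor_class_filter_skips_pair(self):
        # two SNPs whose joint minor class holds 3 accessions
        a = np.array([1] * 33 + [-1] * 60)
        b = np.array([1] * 3 + [-1] * 30 + [1] * 30 + [-1] * 30)
        gm = make_matrix(np.column_stack([a, b]))
        y = np.random.default_rng(0).normal(size=93)
        scan = EpistasisScan(min_class_count=4).fit(gm, y)
        assert scan.counts_["skipped_class"] == 1
        assert scan.counts_["visited"] == 0

    def test_exact_interaction_fit(self):
        # balanced 8-accession design, y = 2 A B exactly
        A = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
        B = np.array([-1, -1, 1, 1, -1, -1, 1, 1])
        gm = make_matrix(np.column_stack([A, B]))
        y = 2.0 * A * B
        scan = EpistasisScan(min_class_count=2, prefilter_p=1.0).fit(gm, y)
        row = scan.results_.iloc[0]
        assert row.b0 == pytest.approx(0.0, abs=1e-12)
        assert row.b1 == pytest.approx(0.0, abs=1e-12)
        assert row.b2 == pytest.approx(0.0, abs=1e-12)
        assert row.b3 == pytest.approx(2.0)
        assert row.b3_01_coding == pytest.approx(8.0)
        assert row.r2_pair == pytest.approx(1.0)

    def test_coefficients_match_statsmodels_oracle(self, small_panel):
        import statsmodels.api as sm
        gm, _ = small_panel
        rng = np.random.default_rng(3)
        y = rng.normal(size=gm.n)
        scan = EpistasisScan(prefilter_p=1.0, min_class_count=4).fit(gm, y)
        sample = scan.results_.sample(25, random_state=0)
        for row in sample.itertuples(index=False):
            A = scan.genotypes_.calls[:, row.idx_a].astype(float)
            B = scan.genotypes_.calls[:, row.idx_b].astype(float)
            X = sm.add_constant(np.column_stack([A, B, A * B]))
            fit = sm.OLS(y, X).fit()
            assert row.b0 == pytest.approx(fit.params[0], abs=1e-10)
            assert row.b3 == pytest.approx(fit.params[3], abs=1e-10)
            assert row.p_ols == pytest.approx(fit.pvalues[3], abs=1e-10)

    def test_class_counts_sum_to_n_and_reconcile(self, small_panel):
        gm, _ = small_panel
        rng = np.random.default_rng(4)
        y = rng.normal(size=gm.n)
        scan = EpistasisScan(prefilter_p=1.0).fit(gm, y)
        c = scan.counts_
        assert c["pairs_total"] == (c["skipped_class"]
                                    + c["skipped_collinear"] + c["visited"])
        counts = scan.results_[["count_mm", "count_mp", "count_pm",
                                "count_pp"]].sum(axis=1)
        assert (counts == gm.n).all()

    def test_collinear_pair_skipped(self):
        A = np.array([1] * 40 + [-1] * 53)
        gm = make_matrix(np.column_stack([A, A]))
        y = np.random.default_rng(1).normal(size=93)
        scan = EpistasisScan().fit(gm, y)
        assert scan.counts_["skipped_collinear"] == 1


class TestMixedRefit:
    def test_identity_kinship_recovers_ols(self, small_panel):
        gm, _ = small_panel
        rng = np.random.default_rng(5)
        mp = eg.make_cancellation_map(5.0, 1.0, 0.3)
        gm2, y, truth = eg.plant_epistatic_pair(
            gm, mp, eg.residual_sd_for_r2(mp, 0.3), seed=6,
            synthesize=True)
        scan = EpistasisScan(prefilter_p=1e-2).fit(gm2, y)
        top = scan.results_.head(10)
        refit = eg.mixed_refit(y, top, scan.genotypes_, np.eye(gm2.n))
        ok = refit.dropna(subset=["p_mixed"])
        logdiff = np.abs(np.log10(ok.p_mixed) - np.log10(ok.p_ols))
        assert np.median(logdiff) < 0.15

    def test_structure_confounding_inflates_mixed_p(self):
        # a null pair whose signal is pure subpopulation mean shift:
        # kinship correction must weaken it
        gm, labels = eg.simulate_panel(PopulationSpec(
            n_accessions=93, n_snps=200, n_subpops=2, fst=0.5, seed=12))
        rng = np.random.default_rng(13)
        y = labels * 2.0 + rng.normal(0, 0.5, gm.n)
        K = eg.compute_kinship(gm)
        scan = EpistasisScan(prefilter_p=1.0).fit(gm, y)
        top = scan.results_.head(20)
        refit = eg.mixed_refit(y, top, scan.genotypes_, K)
        ok = refit.dropna(subset=["p_mixed"])
        assert (ok.p_mixed > ok.p_ols).mean() > 0.8

    def test_b3_symmetric_in_locus_order(self, small_panel):
        gm, _ = small_panel
        rng = np.random.default_rng(7)
        y = rng.normal(size=gm.n)
        K = eg.compute_kinship(gm)
        scan = EpistasisScan(prefilter_p=1.0).fit(gm, y)
        row = scan.results_.head(1)
        swapped = row.rename(columns={"idx_a": "idx_b", "idx_b": "idx_a",
                                      "snp_a": "snp_b", "snp_b": "snp_a"})
        r1 = eg.mixed_refit(y, row, scan.genotypes_, K)
        r2 = eg.mixed_refit(y, swapped, scan.genotypes_, K)
        assert r1.b3_mixed.iloc[0] == pytest.approx(r2.b3_mixed.iloc[0],
                                                    rel=1e-9)


class TestPairBonferroni:
    def test_study_arithmetic(self):
        b = eg.pair_bonferroni(ScanConfig())
        assert b.n_blocks == 12500
        assert b.threshold == pytest.approx(3.2e-10)
        assert b.n_pairs == pytest.approx(78e6, rel=0.01)

    def test_single_block_degenerates_to_alpha(self):
        cfg = ScanConfig(genome_length_bp=1e4, ld_block_bp=1e4)
        assert eg.pair_bonferroni(cfg).threshold == pytest.approx(0.05)


class TestCollapseLinked:
    def _pairs_df(self, items):
        return pd.DataFrame([{"snp_a": f"s{a}", "snp_b": f"s{b}",
                              "idx_a": a, "idx_b": b, "p_ols": p,
                              "p_mixed": p} for a, b, p in items])

    def test_duplicate_via_perfect_ld_merges(self):
        A = np.array([1] * 40 + [-1] * 53)
        B = np.array(([1] * 30 + [-1] * 63))
        rng = np.random.default_rng(2)
        C = np.where(rng.random(93) < 0.4, 1, -1)
        gm = make_matrix(np.column_stack([A, A, B, C]))
        pairs = self._pairs_df([(0, 2, 1e-12), (1, 2, 1e-10)])
        out = eg.collapse_linked(pairs, gm)
        assert out.unique_group.nunique() == 1
        assert out.loc[out.is_representative, "p_mixed"].iloc[0] == 1e-12

    def test_independent_pairs_stay_separate(self):
        rng = np.random.default_rng(3)
        calls = np.where(rng.random((93, 4)) < 0.4, 1, -1)
        gm = make_matrix(calls)
        pairs = self._pairs_df([(0, 1, 1e-12), (2, 3, 1e-11)])
        out = eg.collapse_linked(pairs, gm)
        assert out.unique_group.nunique() == 2

    def test_matches_transitive_closure_oracle(self, small_panel):
        import networkx as nx
        gm, _ = small_panel
        rng = np.random.default_rng(8)
        idx = rng.choice(gm.m, size=(8, 2), replace=False)
        pairs = self._pairs_df([(int(a), int(b), 10.0 ** -rng.integers(9, 15))
                                for a, b in idx])
        out = eg.collapse_linked(pairs, gm, link_r2=0.3)
        g = nx.Graph()
        g.add_nodes_from(range(len(pairs)))
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                a1, b1 = idx[i]
                a2, b2 = idx[j]
                direct = (_ld_r2(gm, a1, a2) >= 0.3
                          and _ld_r2(gm, b1, b2) >= 0.3)
                crossed = (_ld_r2(gm, a1, b2) >= 0.3
                           and _ld_r2(gm, b1, a2) >= 0.3)
                if direct or crossed:
                    g.add_edge(i, j)
        want = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(np.flatnonzero(out.unique_group == u))
               for u in out.unique_group.unique()}
        assert got == want


class TestVarianceExplained:
    def test_exact_pair_reaches_r2_one(self, small_panel):
        gm, _ = small_panel
        mp = eg.make_cancellation_map(5.0, 1.0, 0.3)
        gm2, y, truth = eg.plant_epistatic_pair(gm, mp, 0.0, seed=9,
                                                synthesize=True)
        per_pair, joint = eg.variance_explained(
            y, gm2, [(truth.snp_a, truth.snp_b)], n_boot=50, seed=1)
        assert per_pair.r2_pair.iloc[0] == pytest.approx(1.0)
        assert joint["r2_joint"] == pytest.approx(1.0)

    def test_bootstrap_ci_covers_point_estimate(self, small_panel):
        gm, _ = small_panel
        rng = np.random.default_rng(10)
        y = rng.normal(size=gm.n)
        per_pair, joint = eg.variance_explained(
            y, gm, [(0, 1), (2, 3)], n_boot=300, seed=2)
        assert joint["r2_lo"] <= joint["r2_joint"] + 0.05
        assert joint["r2_joint"] < 0.35  # null signal stays small
        for row in per_pair.itertuples():
            assert row.r2_lo <= row.r2_pair + 0.05 <= row.r2_hi + 0.2


class TestLocalLd:
    def test_leading_snp_always_listed(self, small_panel):
        gm, _ = small_panel
        lead = gm.snps[3].id
        out = eg.local_ld(lead, gm)
        assert lead in set(out.snp)
        assert out.loc[out.snp == lead, "r2"].iloc[0] == 1.0

    def test_window_boundary_excludes_distant_snp(self):
        calls = np.where(np.random.default_rng(4).random((50, 3)) < 0.4,
                         1, -1)
        gm = make_matrix(calls, chroms=["1", "1", "1"],
                         positions=[10000, 14000, 16001])
        out = eg.local_ld(gm.snps[0].id, gm, window_bp=1e4, r2_min=0.0)
        # +-5 kb window around 10 kb: 14,000 in, 16,001 out
        assert set(out.snp) == {gm.snps[0].id, gm.snps[1].id}

    def test_matches_brute_force(self, small_panel):
        gm, _ = small_panel
        lead = gm.snps[10].id
        j0 = 10
        out = eg.local_ld(lead, gm, window_bp=2e4, r2_min=0.2)
        brute = []
        for j, s in enumerate(gm.snps):
            if s.chromosome != gm.snps[j0].chromosome:
                continue
            if abs(s.position - gm.snps[j0].position) > 1e4:
                continue
            r2 = 1.0 if j == j0 else _ld_r2(gm, j0, j)
            if r2 >= 0.2:
                brute.append(s.id)
        assert list(out.snp) == sorted(brute,
                                       key=lambda i: int(i.split("_")[1]))
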
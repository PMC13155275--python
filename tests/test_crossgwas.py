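import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad
from scipy.special import k0

from ironsmoke import crossgwas as cg
from ironsmoke.io import GeneAnnotation, SummaryStats
from ironsmoke.quadform import weighted_chisq_tail
from ironsmoke.simulate import (
    ArchitectureSpec, LdBlockSpec, generate_panel, simulate_summary_pair,
)


def _ss(pvals, betas, eafs=None, trait="t"):
    n = len(pvals)
    eafs = np.full(n, 0.3) if eafs is None else np.asarray(eafs)
    return SummaryStats(trait, pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": "1", "pos": 1000 + 100 * np.arange(n),
        "allele_effect": "A", "allele_other": "G",
        "eaf": eafs, "beta": betas, "se": 0.01, "pval": pvals, "n": 10_000,
    }))


def _mc_oracle(w_pos, w_neg, x, draws, seed):
    """Independent Monte-Carlo oracle for the weighted chi-square tail."""
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 250_000
    w_pos, w_neg = np.asarray(w_pos), np.asarray(w_neg)
    for lo in range(0, draws, chunk):
        n = min(chunk, draws - lo)
        t = np.zeros(n)
        if w_pos.size:
            t += (rng.standard_normal((n, w_pos.size)) ** 2) @ w_pos
        if w_neg.size:
            t -= (rng.standard_normal((n, w_neg.size)) ** 2) @ w_neg
        hits += int((t >= x).sum())
    p = hits / draws
    return p, np.sqrt(max(p * (1 - p), 1e-12) / draws)


class TestSignedRankZ:
    def test_four_snp_worked_example(self):
        ss = _ss([0.001, 0.01, 0.1, 0.5], [0.1, -0.1, 0.1, -0.1])
        sz = cg.signed_rank_z(ss)
        u = np.array([0.125, 0.375, 0.625, 0.875])
        expected = np.array([1, -1, 1, -1]) * stats.norm.ppf(1 - u / 2)
        np.testing.assert_allclose(sz.z, expected, atol=1e-12)

    def test_invariant_to_monotone_p_transform(self):
        p = np.array([0.001, 0.04, 0.3, 0.9])
        b = np.array([1.0, -1, 1, 1])
        z1 = cg.signed_rank_z(_ss(p, b)).z
        z2 = cg.signed_rank_z(_ss(np.sqrt(p), b)).z
        np.testing.assert_allclose(z1, z2)

    def test_low_maf_snp_dropped(self):
        ss = _ss([0.1, 0.2, 0.3], [1.0, 1, 1], eafs=[0.3, 0.005, 0.4])
        sz = cg.signed_rank_z(ss, maf_min=0.01)
        assert len(sz.z) == 2
        assert "rs1" not in sz.snp_id

    def test_degenerate_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cg.signed_rank_z(_ss([0.5, 0.5, 0.5], [1.0, 1, 1]))


class TestWindows:
    def _setup(self):
        panel = generate_panel(200, LdBlockSpec([200], ar_rho=0.3),
                               start_pos=1, spacing_bp=1000, seed=1)
        rng = np.random.default_rng(2)
        ss = _ss(rng.uniform(size=200), rng.normal(size=200))
        ss.table["snp_id"] = panel.snp_id
        ss.table["pos"] = panel.pos
        sz = cg.signed_rank_z(SummaryStats("t", ss.table))
        return panel, sz

    def test_window_geometry_and_inclusive_boundary(self):
        panel, sz = self._setup()
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["G1"], "chrom": ["1"],
            "start": [100_000], "end": [110_000], "strand": ["+"]}))
        wins, _ = cg.build_windows(ann, sz, panel, flank_bp=50_000)
        w = wins[0]
        assert (w.win_start, w.win_end) == (50_000, 160_000)
        pos = {s: p for s, p in zip(panel.snp_id, panel.pos)}
        snp_pos = np.array([pos[s] for s in w.snp_ids])
        assert snp_pos.max() <= 160_000          # SNP at 160 001 excluded
        assert (snp_pos >= 50_000).all()

    def test_gene_without_snps_untested(self):
        panel, sz = self._setup()
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["FAR"], "chrom": ["1"],
            "start": [5_000_000], "end": [5_010_000], "strand": ["+"]}))
        wins, untested = cg.build_windows(ann, sz, panel, flank_bp=1000)
        assert wins == []
        assert untested == ["FAR"]


class TestWeightedChisqTail:
    def test_chi_square_limit(self):
        p, method = weighted_chisq_tail([1.0], [], 3.84)
        assert p == pytest.approx(stats.chi2.sf(3.84, 1), abs=1e-6)
        assert method == "analytic"

    def test_symmetric_weights_at_zero(self):
        p, _ = weighted_chisq_tail([0.5, 0.3], [0.5, 0.3], 0.0)
        assert p == pytest.approx(0.5, abs=1e-10)

    def test_product_normal_closed_form(self):
        # 0.5*(U - V) is distributed as the product of two standard normals
        truth, _ = quad(lambda t: k0(t) / np.pi, 2.0, 60.0)
        p, method = weighted_chisq_tail([0.5], [0.5], 2.0)
        assert method == "analytic"
        assert p == pytest.approx(truth, abs=1e-9)

    def test_random_configurations_match_mc_oracle(self):
        rng = np.random.default_rng(4)
        for i in range(6):
            npos = int(rng.integers(1, 8))
            nneg = int(rng.integers(0, 8))
            w_pos = rng.uniform(0.05, 2.0, npos)
            w_neg = rng.uniform(0.05, 2.0, nneg)
            pilot = (rng.standard_normal((20_000, npos)) ** 2) @ w_pos
            if nneg:
                pilot -= (rng.standard_normal((20_000, nneg)) ** 2) @ w_neg
            x = float(np.quantile(pilot, rng.uniform(0.05, 0.98)))
            p, _ = weighted_chisq_tail(w_pos, w_neg, x)
            mc, se = _mc_oracle(w_pos, w_neg, x, draws=2_000_000, seed=100 + i)
            assert abs(p - mc) <= 3 * se

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_chisq_tail([-1.0], [], 0.0)
        with pytest.raises(ValueError):
            weighted_chisq_tail([], [], 0.0)


class TestCoherence:
    def _window(self, m, rho=0.0, seed=0):
        panel = generate_panel(400, LdBlockSpec([m], ar_rho=rho),
                               start_pos=1000, spacing_bp=100, seed=seed)
        sigma = panel.corr()
        return cg.GeneWindow("G", "1", 0, 10**9, panel.snp_id, sigma)

    def _scores(self, win, za, zb):
        return (cg.SignedZ(win.snp_ids, np.asarray(za, float)),
                cg.SignedZ(win.snp_ids, np.asarray(zb, float)))

    def test_single_snp_matches_product_normal_oracle(self):
        win = cg.GeneWindow("G", "1", 0, 10, np.array(["rs0"]), np.eye(1))
        za, zb = self._scores(win, [2.0], [1.0])
        res = cg.coherence_test(za, zb, win, rho_ov=0.0)
        truth, _ = quad(lambda t: k0(t) / np.pi, 2.0, 60.0)  # P(N1*N2 >= 2)
        assert res.p_coherent == pytest.approx(truth, abs=1e-8)

    def test_negating_one_trait_swaps_tails(self):
        win = self._window(6, rho=0.5, seed=1)
        rng = np.random.default_rng(2)
        za, zb = self._scores(win, rng.normal(size=6), rng.normal(size=6))
        res = cg.coherence_test(za, zb, win, rho_ov=0.2)
        zneg = cg.SignedZ(win.snp_ids, -zb.z)
        res_neg = cg.coherence_test(za, zneg, win, rho_ov=-0.2)
        assert res_neg.p_coherent == pytest.approx(res.p_anticoherent, rel=1e-9)
        assert res_neg.p_anticoherent == pytest.approx(res.p_coherent, rel=1e-9)

    def test_trait_sign_flip_equals_negated_betas(self):
        """Running with trait_sign=-1 must equal running on a study whose
        betas (and thus overlap term) are negated."""
        win = self._window(5, rho=0.6, seed=3)
        rng = np.random.default_rng(4)
        za, zb = self._scores(win, rng.normal(size=5), rng.normal(size=5))
        res_flip = cg.coherence_test(za, zb, win, rho_ov=0.3, trait_sign=-1)
        zneg = cg.SignedZ(win.snp_ids, -zb.z)
        res_neg = cg.coherence_test(za, zneg, win, rho_ov=-0.3, trait_sign=1)
        assert res_flip.p_coherent == pytest.approx(res_neg.p_coherent, rel=1e-12)


class TestRatio:
    def test_proportional_scores_give_exact_ratio(self):
        win = cg.GeneWindow("G", "1", 0, 10**9,
                            np.array([f"s{i}" for i in range(4)]), np.eye(4))
        zb = cg.SignedZ(win.snp_ids, np.array([1.0, -2.0, 0.5, 1.5]))
        za = cg.SignedZ(win.snp_ids, 3.0 * zb.z)
        res = cg.ratio_test(za, zb, win)
        assert res.statistic == pytest.approx(3.0)

    def test_null_pvalues_uniform(self, calib_genome):
        panel, ann = calib_genome
        sub_ann = GeneAnnotation(ann.table.iloc[:400].reset_index(drop=True))
        ss1, ss2, _ = simulate_summary_pair(panel, ann, ArchitectureSpec(),
                                            30_000, 30_000, seed=21)
        za = cg.signed_rank_z(ss1)
        zb = cg.signed_rank_z(ss2)
        wins, _ = cg.build_windows(sub_ann, za, panel, flank_bp=400)
        pv = [cg.ratio_test(za, zb, w).p_fwd for w in wins]
        assert stats.kstest(pv, "uniform").pvalue > 0.01

    def test_zero_outcome_rejected(self):
        win = cg.GeneWindow("G", "1", 0, 10, np.array(["s0"]), np.eye(1))
        za = cg.SignedZ(win.snp_ids, np.array([1.0]))
        zb = cg.SignedZ(win.snp_ids, np.array([0.0]))
        with pytest.raises(ValueError):
            cg.ratio_test(za, zb, win)


class TestArchitecturePower:
    def test_coherent_genes_reach_bonferroni_and_anticoherent_mirror(self, mr_genome):
        panel, ann = mr_genome
        classes = {f"G{j:03d}": "coherent" for j in range(5)}
        classes.update({f"G{j:03d}": "anticoherent" for j in range(5, 10)})
        thresh = cg.bonferroni_threshold(len(ann))
        coh_hits, anti_hits = [], []
        for seed in range(10):
            arch = ArchitectureSpec(classes=classes, tau2=2e-3)
            ss1, ss2, _ = simulate_summary_pair(panel, ann, arch,
                                                100_000, 100_000,
                                                seed=500 + seed)
            scan = cg.run_scan(ss1, ss2, panel, ann, test="coherence",
                               flank_bp=500)
            s = scan.set_index("gene_id")
            coh_hits.append(all(
                s.loc[f"G{j:03d}", "p_coherent"] < thresh for j in range(5)))
            anti_hits.append(all(
                s.loc[f"G{j:03d}", "p_anticoherent"] < thresh
                for j in range(5, 10)))
        assert np.mean(coh_hits) >= 0.8
        assert np.mean(anti_hits) >= 0.8


class TestMultipleTesting:
    def test_bonferroni_printed_thresholds(self):
        assert float(f"{cg.bonferroni_threshold(18_344):.2e}") == 2.73e-06
        assert cg.bonferroni_threshold(5) == pytest.approx(0.01)
        assert cg.bonferroni_threshold(1) == pytest.approx(0.05)

    def test_clusters_merge_overlapping_windows(self):
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["A", "B", "C", "D"], "chrom": "1",
            "start": [100_000, 160_000, 220_000, 900_000],
            "end": [110_000, 170_000, 230_000, 910_000], "strand": "+"}))
        res = pd.DataFrame({"gene_id": ["A", "B", "C", "D"],
                            "p_coherent": [1e-9, 1e-9, 1e-9, 1e-9]})
        clusters = cg.cluster_significant(res, ann, 1e-6)
        # windows of A-B and B-C overlap (chain), D is isolated
        assert sorted(map(tuple, clusters)) == [("A", "B", "C"), ("D",)]

    def test_nonsignificant_genes_ignored(self):
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["A", "B"], "chrom": "1",
            "start": [100_000, 120_000], "end": [110_000, 130_000],
            "strand": "+"}))
        res = pd.DataFrame({"gene_id": ["A", "B"], "p_coherent": [1e-9, 0.5]})
        assert cg.cluster_significant(res, ann, 1e-6) == [["A"]]

    def test_candidate_mode_threshold_and_warning(self, caplog):
        res = pd.DataFrame({"gene_id": ["DRD2", "PPP1R1B", "X"],
                            "p_coherent": [0.001, 0.5, 0.9]})
        sub, thresh = cg.candidate_mode(res, ["DRD2", "PPP1R1B", "MISSING"])
        assert len(sub) == 2
        assert thresh == pytest.approx(0.05 / 2)

    def test_exclude_genes_identity_and_idempotence(self):
        res = pd.DataFrame({"gene_id": ["A", "B", "C"], "p_coherent": [1, 1, 1]})
        assert cg.exclude_genes(res, []).equals(res)
        once = cg.exclude_genes(res, ["B"])
        twice = cg.exclude_genes(once, ["B"])
        assert once.equals(twice)
        assert list(once["gene_id"]) == ["A", "C"]
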
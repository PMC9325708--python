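"""Heritability screen, weight training, pQTL scans, clumping, pi1."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan import qtl
from pleioscan.io import GenotypePanel
from pleioscan.simulate import SimulationConfig, cis_architecture, simulate_genome


@pytest.fixture(scope="session")
def no_covariates():
    def make(n):
        return pd.DataFrame(index=range(n))
    return make


def _toy_panel(dosages, positions, chrom="1"):
    m = dosages.shape[1]
    snps = pd.DataFrame(
        {"SNP": [f"t{k}" for k in range(m)], "CHR": chrom, "BP": positions,
         "A1": "A", "A2": "G"}
    )
    return GenotypePanel(snps=snps, dosages=dosages.astype(np.int8))


GENES = pd.DataFrame({"GENE": ["GX"], "CHR": ["1"], "START": [1_000_000], "END": [1_010_000]})


class TestCisWindow:
    @pytest.mark.parametrize("bp,included", [(500_000, True), (499_999, False),
                                             (1_510_000, True), (1_510_001, False)])
    def test_boundaries_inclusive(self, bp, included):
        snps = pd.DataFrame({"SNP": ["a"], "CHR": ["1"], "BP": [bp]})
        got = qtl.cis_window("GX", GENES, snps)
        assert (len(got) == 1) == included

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        snps = pd.DataFrame(
            {"SNP": [f"s{k}" for k in range(10)],
             "CHR": rng.choice(["1", "2"], size=10),
             "BP": rng.integers(1, 2_500_000, size=10)}
        )
        got = set(qtl.cis_window("GX", GENES, snps)["SNP"])
        want = {
            r.SNP for r in snps.itertuples()
            if r.CHR == "1" and 500_000 <= r.BP <= 1_510_000
        }
        assert got == want

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            qtl.cis_window("NOPE", GENES, pd.DataFrame({"SNP": [], "CHR": [], "BP": []}))


class TestHeritability:
    def test_noise_free_single_snp(self, no_covariates):
        rng = np.random.default_rng(1)
        n = 200
        dos = rng.binomial(2, 0.3, size=(n, 5))
        panel = _toy_panel(dos, 1_000_000 + np.arange(5) * 1000)
        y = (dos[:, 2] - dos[:, 2].mean()) / dos[:, 2].std()
        est = qtl.estimate_cis_h2(panel, y, no_covariates(n), "GX", GENES)
        assert est.h2 == pytest.approx(1.0, abs=0.15)
        assert est.p < 1e-6
        assert est.heritable

    def test_null_calibration_one_percent(self, no_covariates):
        """Permutation oracle: heritable rate ~1% at p<0.01 on null genes."""
        rng = np.random.default_rng(2)
        n = 150
        dos = rng.binomial(2, 0.3, size=(n, 20))
        panel = _toy_panel(dos, 1_000_000 + np.arange(20) * 1000)
        hits, ps = 0, []
        for rep in range(200):
            y = rng.standard_normal(n)
            est = qtl.estimate_cis_h2(panel, y, no_covariates(n), "GX", GENES)
            ps.append(est.p)
            hits += est.p < 0.01
        assert hits / 200 <= 0.04
        assert 0.35 < np.mean(ps) < 0.65

    def test_planted_h2_recovered(self, no_covariates):
        cfg = SimulationConfig(seed=9, n_blocks=25, snps_per_block=30, n_genes=25, n_cohort=500)
        layout, _, cohort = simulate_genome(cfg)
        from pleioscan.simulate import PlantedTruth, simulate_molecular_traits

        truth = PlantedTruth(traits=["T1"], rg_matrix=pd.DataFrame([[1.0]], index=["T1"], columns=["T1"]))
        ab, cov = simulate_molecular_traits(layout, truth, cfg, cohort)
        ests = [
            qtl.estimate_cis_h2(cohort, ab[g], cov, g, layout.genes).h2
            for g in layout.genes["GENE"]
        ]
        assert 0.22 < np.mean(ests) < 0.38

    def test_constant_abundance_rejected(self, no_covariates):
        panel = _toy_panel(np.ones((40, 3), int), 1_000_000 + np.arange(3))
        with pytest.raises(ValueError):
            qtl.estimate_cis_h2(panel, np.ones(40), no_covariates(40), "GX", GENES)

    def test_hla_exclusion(self, no_covariates):
        genes = pd.DataFrame({"GENE": ["H1"], "CHR": ["6"], "START": [26_000_000], "END": [26_010_000]})
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.3, size=(100, 4))
        panel = _toy_panel(dos, 26_000_000 + np.arange(4) * 100, chrom="6")
        y = (dos[:, 0] - dos[:, 0].mean()) / dos[:, 0].std()
        est = qtl.estimate_cis_h2(panel, y, no_covariates(100), "H1", genes)
        assert est.hla_excluded and not est.heritable


class TestWeights:
    def test_single_causal_noise_free(self, no_covariates):
        rng = np.random.default_rng(4)
        n = 300
        dos = rng.binomial(2, 0.4, size=(n, 8))
        panel = _toy_panel(dos, 1_000_000 + np.arange(8) * 1000)
        x = panel.standardized()
        y = x[:, 3]
        ws = qtl.fit_weights(panel, y, no_covariates(n), "GX", GENES, h2_guess=0.9, seed=1)
        assert ws is not None
        assert ws.cv_r2 > 0.98
        pred = panel.standardized()[:, panel.index_of(ws.snps["SNP"])] @ ws.weights
        assert np.corrcoef(pred, y)[0, 1] > 0.999

    def test_null_gene_dropped(self, no_covariates):
        rng = np.random.default_rng(5)
        n = 200
        dos = rng.binomial(2, 0.4, size=(n, 10))
        panel = _toy_panel(dos, 1_000_000 + np.arange(10) * 1000)
        y = rng.standard_normal(n)
        assert qtl.fit_weights(panel, y, no_covariates(n), "GX", GENES, seed=1) is None

    def test_two_causal_in_ld_prediction(self, small_study):
        """Truth-manifest oracle: predictions correlate > 0.9 with the true
        genetic value on genes simulated with cis h2 = 0.3."""
        st = small_study
        cov = st.covariates
        good = 0
        for gene in st.layout.genes["GENE"][:6]:
            idx, beta = cis_architecture(st.layout, st.config, gene)
            g_true = st.cohort.standardized()[:, idx] @ beta
            ws = qtl.fit_weights(st.cohort, st.abundance[gene], cov, gene, st.layout.genes, seed=2)
            if ws is None:
                continue
            pred = st.cohort.standardized()[:, st.cohort.index_of(ws.snps["SNP"])] @ ws.weights
            good += np.corrcoef(pred, g_true)[0, 1] > 0.9
        assert good >= 5

    def test_sample_order_invariance(self, no_covariates):
        rng = np.random.default_rng(6)
        n = 200
        dos = rng.binomial(2, 0.4, size=(n, 6))
        panel = _toy_panel(dos, 1_000_000 + np.arange(6) * 1000)
        y = panel.standardized()[:, 1] * 0.7 + 0.3 * rng.standard_normal(n)
        perm = rng.permutation(n)
        panel2 = _toy_panel(dos[perm], 1_000_000 + np.arange(6) * 1000)
        a = qtl.fit_weights(panel, y, no_covariates(n), "GX", GENES, seed=3)
        b = qtl.fit_weights(panel2, y[perm], no_covariates(n), "GX", GENES, seed=3)
        # CV fold membership shifts with row order, so sparsity patterns may
        # differ; the fitted genetic predictor itself must be stable
        pred_a = panel.standardized()[:, panel.index_of(a.snps["SNP"])] @ a.weights
        pred_b = panel2.standardized()[:, panel2.index_of(b.snps["SNP"])] @ b.weights
        inv = np.empty(n, int)
        inv[perm] = np.arange(n)
        assert np.corrcoef(pred_a, pred_b[inv])[0, 1] > 0.98


class TestCisScan:
    def test_exact_association_p_zero(self, no_covariates):
        rng = np.random.default_rng(7)
        n = 200
        dos = rng.binomial(2, 0.4, size=(n, 5))
        panel = _toy_panel(dos, 1_000_000 + np.arange(5) * 1000)
        ab = pd.DataFrame({"GX": panel.standardized()[:, 2]})
        rec = qtl.cis_pqtl_scan(panel, ab, no_covariates(n), GENES)
        assert rec.loc[rec["SNP"] == "t2", "P"].iloc[0] < 1e-250
        assert rec.loc[rec["SNP"] == "t2", "LEAD"].iloc[0]

    def test_null_min_p_matches_permutation(self, no_covariates):
        """Permutation oracle for the per-gene minimum p under the null."""
        rng = np.random.default_rng(8)
        n, m = 120, 30
        dos = rng.binomial(2, 0.4, size=(n, m))
        panel = _toy_panel(dos, 1_000_000 + np.arange(m) * 1000)
        y0 = rng.standard_normal(n)
        minps = []
        for rep in range(200):
            ab = pd.DataFrame({"GX": rng.permutation(y0)})
            rec = qtl.cis_pqtl_scan(panel, ab, no_covariates(n), GENES)
            minps.append(rec["P"].min())
        # independent brute-force oracle of the same null
        x = panel.standardized()
        oracle = []
        for rep in range(200):
            y = rng.permutation(y0)
            yr = (y - y.mean()) / y.std()
            r = x.T @ yr / n
            t = r * np.sqrt((n - 2) / (1 - r**2))
            oracle.append(np.min(2 * stats.t.sf(np.abs(t), n - 2)))
        ks = stats.ks_2samp(minps, oracle)
        assert ks.pvalue > 0.01

    def test_planted_effect_power(self, no_covariates):
        """Analytic power oracle: |z| ~ beta*sqrt(n) for standardized beta 0.5."""
        rng = np.random.default_rng(9)
        n = 500
        dos = rng.binomial(2, 0.4, size=(n, 5))
        panel = _toy_panel(dos, 1_000_000 + np.arange(5) * 1000)
        x = panel.standardized()
        y = 0.5 * x[:, 1] + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        rec = qtl.cis_pqtl_scan(panel, pd.DataFrame({"GX": y}), no_covariates(n), GENES)
        z = np.abs(rec.loc[rec["SNP"] == "t1", "BETA"] / rec.loc[rec["SNP"] == "t1", "SE"]).iloc[0]
        assert 8 < z < 16

    def test_rank_deficient_covariates_named(self, no_covariates):
        rng = np.random.default_rng(10)
        n = 100
        dos = rng.binomial(2, 0.4, size=(n, 3))
        panel = _toy_panel(dos, 1_000_000 + np.arange(3) * 1000)
        c = rng.standard_normal(n)
        cov = pd.DataFrame({"C1": c, "C2": 2 * c})
        with pytest.raises(ValueError, match="C2"):
            qtl.cis_pqtl_scan(panel, pd.DataFrame({"GX": rng.standard_normal(n)}), cov, GENES)


class TestClump:
    def _ld_pair_panel(self, bp2, n=2000, seed=0, flip_frac=0.05):
        rng = np.random.default_rng(seed)
        d1 = rng.binomial(2, 0.4, size=n)
        d2 = d1.copy()
        flip = rng.random(n) < flip_frac
        d2[flip] = rng.binomial(2, 0.4, size=int(flip.sum()))  # r2 ~ 0.9
        snps = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "BP": [100_000, bp2], "A1": "A", "A2": "G"})
        return GenotypePanel(snps=snps, dosages=np.column_stack([d1, d2]).astype(np.int8))

    def _ss(self, zs, panel):
        return panel.snps.assign(Z=zs, N=10_000, FREQ=0.3)

    def test_correlated_within_window_one_kept(self):
        panel = self._ld_pair_panel(200_000)
        ss = self._ss([7.0, 6.5], panel)
        kept = qtl.clump_gwas_hits(ss, panel)
        assert list(kept["SNP"]) == ["a"]

    def test_correlated_outside_window_both_kept(self):
        panel = self._ld_pair_panel(500_000)  # 400 kb apart > 250 kb
        ss = self._ss([7.0, 6.5], panel)
        kept = qtl.clump_gwas_hits(ss, panel)
        assert set(kept["SNP"]) == {"a", "b"}

    def test_toy_block_matches_brute_force(self):
        cfg = SimulationConfig(seed=12, n_blocks=1, snps_per_block=6, n_genes=1,
                               snp_spacing_bp=50_000, n_panel=3000)
        _, panel, _ = simulate_genome(cfg)
        rng = np.random.default_rng(1)
        z = np.array([9.0, 6.2, 7.5, 6.0, 8.1, 5.9]) * rng.choice([1, -1], 6)
        ss = panel.snps.assign(Z=z, N=10_000)
        kept = set(qtl.clump_gwas_hits(ss, panel)["SNP"])
        # brute-force re-implementation of the stated greedy rule
        x = panel.standardized()
        order = np.argsort(-np.abs(z))
        want = []
        for j in order:
            ok = True
            for k in want:
                dist = abs(panel.snps["BP"].iloc[j] - panel.snps["BP"].iloc[k])
                r2 = np.corrcoef(x[:, j], x[:, k])[0, 1] ** 2
                if dist <= 250_000 and r2 >= 0.5:
                    ok = False
            if ok:
                want.append(j)
        assert kept == set(panel.snps["SNP"].iloc[want])


class TestTransScan:
    @pytest.fixture(scope="class")
    def trans_setup(self):
        rng = np.random.default_rng(13)
        n = 500
        dos = rng.binomial(2, 0.3, size=(n, 3))
        snps = pd.DataFrame(
            {"SNP": ["near", "far", "other"], "CHR": ["1", "1", "2"],
             "BP": [600_000, 5_000_000, 100_000], "A1": "A", "A2": "G"}
        )
        panel = GenotypePanel(snps=snps, dosages=dos.astype(np.int8))
        x = panel.standardized()
        ab = pd.DataFrame({"GX": 0.9 * x[:, 0] + 0.9 * x[:, 1] + 0.9 * x[:, 2]
                           + 0.1 * rng.standard_normal(n)})
        clumped = pd.DataFrame({"SNP": ["near", "far", "other"]})
        scan = qtl.trans_pqtl_scan(clumped, panel, ab, pd.DataFrame(index=range(n)), GENES)
        return scan

    def test_cis_distance_not_trans(self, trans_setup):
        rec = trans_setup.set_index("SNP").loc["near"]
        assert rec["P"] < 1e-10 and not rec["TRANS"]

    def test_other_chromosome_is_trans(self, trans_setup):
        rec = trans_setup.set_index("SNP").loc["other"]
        assert rec["P"] < 1e-10 and rec["TRANS"] and rec["SIGNIFICANT"]

    def test_far_same_chromosome_is_trans(self, trans_setup):
        rec = trans_setup.set_index("SNP").loc["far"]
        assert rec["TRANS"] and rec["DISTANCE"] > 500_000

    def test_null_false_positive_rate(self):
        """~0 false positives at 5e-8 over 1000 null SNP-gene tests."""
        rng = np.random.default_rng(14)
        n = 400
        dos = rng.binomial(2, 0.3, size=(n, 10))
        snps = pd.DataFrame({"SNP": [f"q{k}" for k in range(10)], "CHR": "2",
                             "BP": 1000 + np.arange(10) * 1000, "A1": "A", "A2": "G"})
        panel = GenotypePanel(snps=snps, dosages=dos.astype(np.int8))
        ab = pd.DataFrame({f"G{k}": rng.standard_normal(n) for k in range(100)})
        genes = pd.DataFrame({"GENE": list(ab.columns), "CHR": "1",
                              "START": 1_000_000, "END": 1_010_000})
        scan = qtl.trans_pqtl_scan(pd.DataFrame({"SNP": snps["SNP"]}), panel, ab,
                                   pd.DataFrame(index=range(n)), genes)
        assert scan["SIGNIFICANT"].sum() == 0


class TestPi1:
    def test_all_signal(self):
        est = qtl.estimate_pi1(np.full(50, 1e-12))
        assert est.pi1 == pytest.approx(1.0)

    def test_uniform_null(self):
        rng = np.random.default_rng(15)
        est = qtl.estimate_pi1(rng.uniform(size=1000))
        assert est.pi1 == pytest.approx(0.0, abs=0.1)

    def test_mixture_recovery(self):
        rng = np.random.default_rng(16)
        signal = rng.beta(0.05, 10, size=600)  # concentrated near 0
        nulls = rng.uniform(size=400)
        est = qtl.estimate_pi1(np.concatenate([signal, nulls]))
        assert est.pi1 == pytest.approx(0.6, abs=0.15)

    def test_too_few_pvalues(self):
        with pytest.raises(ValueError):
            qtl.estimate_pi1(np.ones(10))
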
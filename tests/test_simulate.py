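"""Generator tests: determinism, LD targets, planted-truth recovery oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleioscan._rng import stage_rng
from pleioscan.io import read_sumstats, read_table, read_vcf
from pleioscan.simulate import (
    AnnotationSpec,
    ConfigurationError,
    PlantedTruth,
    SimulationConfig,
    _sample_dosages,
    cis_architecture,
    default_layout,
    dosage_ld_matrix,
    simulate_all_gwas,
    simulate_annotations,
    simulate_genome,
    simulate_molecular_traits,
    simulate_ppi,
    simulate_study,
    write_study,
)


def _cfg(**kw):
    base = dict(seed=5, n_blocks=4, snps_per_block=25, n_genes=4, n_panel=200, n_cohort=150)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenome:
    def test_same_seed_byte_identical(self):
        a = simulate_genome(_cfg())
        b = simulate_genome(_cfg())
        assert np.array_equal(a[1].dosages, b[1].dosages)
        assert np.array_equal(a[2].dosages, b[2].dosages)

    def test_rho_zero_independence(self):
        cfg = _cfg(rho=0.0, n_panel=5000, n_blocks=1, snps_per_block=20)
        _, panel, _ = simulate_genome(cfg)
        x = panel.standardized()
        r_adj = [np.corrcoef(x[:, j], x[:, j + 1])[0, 1] for j in range(19)]
        assert np.all(np.abs(r_adj) < 0.05)

    def test_adjacent_correlation_tracks_exact_value(self):
        """Mean empirical adjacent-SNP correlation matches the copula-exact
        dosage LD within +/-0.03, averaged over 20 seeds."""
        diffs = []
        for seed in range(20):
            cfg = _cfg(seed=seed, n_blocks=1, snps_per_block=20, n_panel=5000)
            layout, panel, _ = simulate_genome(cfg)
            exact = np.diag(layout.block_ld(0), 1)
            x = panel.standardized()
            emp = np.array([np.corrcoef(x[:, j], x[:, j + 1])[0, 1] for j in range(19)])
            diffs.append((emp - exact).mean())
        assert abs(np.mean(diffs)) < 0.03

    def test_ld_matrices_positive_semidefinite(self):
        layout, _, _ = simulate_genome(_cfg())
        for b in range(len(layout.blocks)):
            assert np.linalg.eigvalsh(layout.block_ld(b)).min() >= -1e-8

    def test_dosage_ld_matches_bivariate_normal(self):
        maf = np.array([0.25, 0.1])
        got = dosage_ld_matrix(maf, 0.9)[0, 1]
        t = stats.norm.ppf(maf)
        phi2 = stats.multivariate_normal(mean=[0, 0], cov=[[1, 0.9], [0.9, 1]]).cdf(t)
        want = (phi2 - maf[0] * maf[1]) / np.sqrt(np.prod(maf * (1 - maf)))
        assert got == pytest.approx(want, abs=1e-6)

    def test_nonpositive_block_size_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(snps_per_block=0)


class TestMolecular:
    def test_h2_zero_abundance_independent_of_genotype(self):
        cfg = _cfg(cis_h2=0.0, n_cohort=300)
        layout, _, cohort = simulate_genome(cfg)
        truth = _null_truth(layout)
        ab, _ = simulate_molecular_traits(layout, truth, cfg, cohort)
        x = cohort.standardized()
        pvals = []
        for gene in layout.genes["GENE"]:
            idx = np.flatnonzero(
                (layout.snp_table["CHR"] == layout.genes.set_index("GENE").loc[gene, "CHR"]).to_numpy()
            )
            y = ab[gene].to_numpy()
            for j in idx[:10]:
                r = np.corrcoef(x[:, j], y)[0, 1]
                tstat = r * np.sqrt((len(y) - 2) / (1 - r**2))
                pvals.append(2 * stats.t.sf(abs(tstat), len(y) - 2))
        assert 0.35 < np.mean(pvals) < 0.65  # uniform p-values

    def test_h2_one_single_snp_equals_genotype(self):
        cfg = _cfg(cis_h2=1.0, n_causal_cis=1, covariate_share=0.0)
        layout, _, cohort = simulate_genome(cfg)
        truth = _null_truth(layout)
        ab, _ = simulate_molecular_traits(layout, truth, cfg, cohort)
        gene = layout.genes["GENE"].iloc[0]
        idx, _ = cis_architecture(layout, cfg, gene)
        x = cohort.standardized()[:, idx[0]]
        assert abs(np.corrcoef(ab[gene], x)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_realized_h2_variance_ratio(self):
        """Variance-ratio oracle: realized var(cis genetic)/var(y) near 0.3."""
        cfg = _cfg(n_blocks=25, snps_per_block=30, n_genes=25, n_cohort=500)
        layout, _, cohort = simulate_genome(cfg)
        truth = _null_truth(layout)
        ab, _ = simulate_molecular_traits(layout, truth, cfg, cohort)
        x = cohort.standardized()
        ratios = []
        for gene in layout.genes["GENE"]:
            idx, beta = cis_architecture(layout, cfg, gene)
            g = x[:, idx] @ beta
            y = ab[gene].to_numpy()
            b = np.polyfit(g, y, 1)[0]
            ratios.append(np.var(b * g) / np.var(y))
        assert 0.25 < np.mean(ratios) < 0.35

    def test_h2_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(cis_h2=1.5)


def _null_truth(layout, traits=("T1", "T2")):
    traits = list(traits)
    rg = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    return PlantedTruth(traits=traits, rg_matrix=rg)


class TestGwas:
    def test_null_mean_chisq_near_one(self):
        cfg = SimulationConfig(seed=2, n_genes=10, h2_trait=0.0)
        layout = default_layout(cfg)
        truth = _null_truth(layout)
        ss = simulate_all_gwas(layout, truth, cfg)
        chi = ss["T1"]["Z"].to_numpy() ** 2
        assert abs(chi.mean() - 1.0) < 0.05  # 20k SNPs

    def test_identical_effects_give_correlated_z(self):
        """Two traits with rg = 1 share every planted effect; z-scores at
        strongly causal SNPs approach equality as noise becomes negligible."""
        cfg = _cfg(h2_trait=0.0, n_gwas=10_000_000)
        layout = default_layout(cfg)
        traits = ["A", "B"]
        rg = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=traits, columns=traits)
        gene = layout.genes["GENE"].iloc[0]
        truth = PlantedTruth(traits=traits, rg_matrix=rg)
        truth.pleiotropic_links = [
            type("L", (), {"gene": gene, "trait": t, "b_xy": 0.5})() for t in traits
        ]
        ss = simulate_all_gwas(layout, truth, cfg)
        idx, _ = cis_architecture(layout, cfg, gene)
        za = ss["A"]["Z"].to_numpy()[idx]
        zb = ss["B"]["Z"].to_numpy()[idx]
        assert np.allclose(za / zb, 1.0, atol=1e-2)

    def test_unknown_trait_raises(self):
        cfg = _cfg()
        layout = default_layout(cfg)
        truth = _null_truth(layout)
        from pleioscan.simulate import simulate_gwas

        with pytest.raises(KeyError):
            simulate_gwas(layout, truth, cfg, "NOPE")


class TestPpi:
    def _truth(self, universe, fold, n_a=100, n_b=50):
        t = _null_truth_universe()
        t.planted_ppi_fold = fold
        t.ppi_set_a = universe[:n_a]
        t.ppi_set_b = universe[n_a : n_a + n_b]
        return t

    def test_fold_one_matches_background(self):
        uni = [f"N{k}" for k in range(2000)]
        cfg = SimulationConfig(seed=1, ppi_background_q=0.02)
        truth = self._truth(uni, 1.0, n_a=200, n_b=50)
        edges = simulate_ppi(truth, cfg, uni)
        ratio = _interset_ratio(edges, truth, uni, cfg.ppi_background_q)
        assert 0.8 < ratio < 1.2

    def test_q_zero_no_edges(self):
        uni = [f"N{k}" for k in range(100)]
        cfg = SimulationConfig(seed=1, ppi_background_q=0.0)
        edges = simulate_ppi(self._truth(uni, 5.0, 20, 10), cfg, uni)
        assert edges.empty

    def test_planted_fold_recovered(self):
        """Counting oracle over 20 seeds: realized inter-set density over
        background within +/-0.5 of the planted 2.5 at |A|=400, |B|=40."""
        uni = [f"N{k}" for k in range(2000)]
        ratios = []
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, ppi_background_q=0.01)
            truth = self._truth(uni, 2.5, n_a=400, n_b=40)
            edges = simulate_ppi(truth, cfg, uni)
            ratios.append(_interset_ratio(edges, truth, uni, cfg.ppi_background_q))
        assert abs(np.mean(ratios) - 2.5) < 0.5

    def test_negative_fold_rejected(self):
        uni = [f"N{k}" for k in range(50)]
        truth = self._truth(uni, 1.0, 10, 5)
        truth.planted_ppi_fold = -1.0
        with pytest.raises(ConfigurationError):
            simulate_ppi(truth, SimulationConfig(seed=0), uni)

    def test_no_self_loops_or_duplicates(self, small_study):
        e = small_study.ppi
        assert (e["SYMBOL_A"] != e["SYMBOL_B"]).all()
        key = e.apply(lambda r: tuple(sorted((r["SYMBOL_A"], r["SYMBOL_B"]))), axis=1)
        assert not key.duplicated().any()


def _null_truth_universe():
    traits = ["T1"]
    return PlantedTruth(traits=traits, rg_matrix=pd.DataFrame([[1.0]], index=traits, columns=traits))


def _interset_ratio(edges, truth, universe, q):
    a, b = set(truth.ppi_set_a), set(truth.ppi_set_b)
    cross = sum(
        1 for x, y in zip(edges["SYMBOL_A"], edges["SYMBOL_B"])
        if (x in a and y in b) or (x in b and y in a)
    )
    density = cross / (len(a) * len(b))
    return density / q


class TestAnnotations:
    def test_set_equals_universe_gives_fold_one(self):
        uni = [f"G{k}" for k in range(500)]
        truth = _null_truth_universe()
        truth.annotation_target = uni[:50]
        truth.planted_annotation_overlap = {"all": AnnotationSpec(size=500, target_fraction=1.0)}
        sets = simulate_annotations(truth, SimulationConfig(seed=0), uni)
        assert set(sets["all"]) == set(uni)
        from pleioscan.ppi import set_fold_enrichment

        res = set_fold_enrichment(truth.annotation_target, sets["all"], len(uni))
        assert res.fold == pytest.approx(1.0)
        assert res.hypergeom_p == pytest.approx(1.0)

    def test_planted_fraction_arithmetic(self):
        """fold ~= fraction/(K/N) for a 118-gene target, 1137-of-20338 set."""
        uni = [f"G{k:05d}" for k in range(20338)]
        truth = _null_truth_universe()
        truth.annotation_target = uni[:118]
        truth.planted_annotation_overlap = {"mito": AnnotationSpec(size=1137, target_fraction=0.8)}
        sets = simulate_annotations(truth, SimulationConfig(seed=0), uni)
        from pleioscan.ppi import set_fold_enrichment

        res = set_fold_enrichment(truth.annotation_target, sets["mito"], len(uni))
        expected = 0.8 / (1137 / 20338)
        assert res.fold == pytest.approx(expected, rel=0.15)

    def test_oversized_set_rejected(self):
        uni = [f"G{k}" for k in range(10)]
        truth = _null_truth_universe()
        truth.planted_annotation_overlap = {"big": AnnotationSpec(size=11, target_fraction=0.0)}
        with pytest.raises(ConfigurationError):
            simulate_annotations(truth, SimulationConfig(seed=0), uni)


class TestWriteStudy:
    def test_round_trip(self, tiny_study, tmp_path):
        manifest = write_study(tiny_study, tmp_path)
        panel = read_vcf(manifest["panel_vcf"])
        assert np.array_equal(panel.dosages, tiny_study.panel.dosages)
        assert list(panel.snps["SNP"]) == list(tiny_study.panel.snps["SNP"])
        ab = read_table(manifest["abundance"], index_col=0)
        pd.testing.assert_frame_equal(ab, tiny_study.abundance, check_exact=False, atol=1e-12)
        ss = read_sumstats(manifest["sumstats:T1"])
        np.testing.assert_allclose(ss["Z"], tiny_study.sumstats["T1"]["Z"], atol=1e-12)

    def test_empty_trait_list(self, tmp_path):
        cfg = _cfg()
        layout, panel, cohort = simulate_genome(cfg)
        truth = PlantedTruth(traits=[], rg_matrix=pd.DataFrame())
        ab, cov = simulate_molecular_traits(layout, truth, cfg, cohort)
        from pleioscan.simulate import SyntheticStudy

        study = SyntheticStudy(
            config=cfg, layout=layout, truth=truth, panel=panel, cohort=cohort,
            abundance=ab, covariates=cov, sumstats={}, ppi=pd.DataFrame(columns=["SYMBOL_A", "SYMBOL_B", "EVIDENCE_TYPE"]),
            ppi_universe=[], annotations={},
        )
        manifest = write_study(study, tmp_path)
        assert not any(k.startswith("sumstats:") for k in manifest)

    def test_study_parses_with_pipeline_readers(self, tiny_study, tmp_path):
        from pleioscan.pipeline import load_study

        write_study(tiny_study, tmp_path)
        bundle = load_study(tmp_path)
        assert bundle.cohort.n_samples == tiny_study.cohort.n_samples
        assert set(bundle.sumstats) == set(tiny_study.sumstats)
        assert list(bundle.genes["GENE"]) == list(tiny_study.layout.genes["GENE"])
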
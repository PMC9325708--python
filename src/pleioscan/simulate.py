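"""Synthetic study generator with known planted truth.

Emulates, at desk scale, every input the integration pipeline consumes:

* block-diagonal LD genotypes (Gaussian-copula haplotypes thresholded at
  MAF quantiles, AR(1) latent correlation within a block),
* a molecular cohort with cis-heritable abundances, optional trans effects,
  covariates and noise,
* GWAS summary statistics simulated at summary level: per LD block the
  z-vector is multivariate normal with mean sqrt(N)*R*a and covariance R,
  where a holds polygenic effects (drawn jointly across traits with the
  target genetic correlations), mediated effects (b_xy times the cis pQTL
  effects of pleiotropic genes), linkage decoys (a trait-causal SNP in LD
  with the protein-causal SNP) and trans-mediated effects,
* a PPI edge list with a planted excess of edges between two designated
  gene sets, and GMT annotation sets with a planted in-set fraction.

All LD used for the summary-level simulation is the *dosage-scale*
population correlation implied by the copula (computed exactly by
quadrature), so LD scores and LD submatrices estimated downstream from the
simulated panel converge to the matrices that generated the z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .io import (
    GenotypePanel,
    write_gmt,
    write_json,
    write_sumstats,
    write_table,
    write_vcf,
)

PHYSICAL_EVIDENCE = [
    "physical association",
    "association",
    "colocalization",
    "direct interaction",
]
NONPHYSICAL_EVIDENCE = ["genetic interaction", "synthetic genetic interaction"]


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types


@dataclass
class LdBlock:
    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    maf: np.ndarray  # in [0.05, 0.5]
    rho: float  # latent AR(1) parameter

    @property
    def n_snps(self) -> int:
        return len(self.positions)


@dataclass
class GenomeLayout:
    blocks: list[LdBlock]
    genes: pd.DataFrame  # GENE CHR START END

    def __post_init__(self) -> None:
        per_chrom: dict[str, int] = {}
        for b in self.blocks:
            if b.n_snps <= 0:
                raise ConfigurationError("empty LD block")
            if np.any(np.diff(b.positions) <= 0):
                raise ConfigurationError("positions not strictly increasing within block")
            if np.any((b.maf < 0.05) | (b.maf > 0.5)):
                raise ConfigurationError("MAF outside [0.05, 0.5]")
            last = per_chrom.get(b.chrom, 0)
            if b.positions[0] <= last:
                raise ConfigurationError("blocks overlap along chromosome")
            per_chrom[b.chrom] = int(b.positions[-1])
        self._ld_cache: dict[int, np.ndarray] = {}
        self._factor_cache: dict[int, np.ndarray] = {}
        snp_rows = []
        for bi, b in enumerate(self.blocks):
            for k in range(b.n_snps):
                snp_rows.append((f"rs{bi:03d}_{k:03d}", b.chrom, int(b.positions[k]), float(b.maf[k]), bi, k))
        self.snp_table = pd.DataFrame(snp_rows, columns=["SNP", "CHR", "BP", "MAF", "BLOCK", "IDX"])
        chrom_of_gene = self.genes.set_index("GENE")["CHR"]
        if chrom_of_gene.index.duplicated().any():
            raise ConfigurationError("duplicate gene symbols")
        if (self.genes["START"] > self.genes["END"]).any():
            raise ConfigurationError("gene START > END")

    @property
    def n_snps(self) -> int:
        return len(self.snp_table)

    def block_slices(self) -> list[slice]:
        out, start = [], 0
        for b in self.blocks:
            out.append(slice(start, start + b.n_snps))
            start += b.n_snps
        return out

    def block_ld(self, bi: int) -> np.ndarray:
        """Dosage-scale population LD (correlation) matrix for block ``bi``."""
        if bi not in self._ld_cache:
            b = self.blocks[bi]
            self._ld_cache[bi] = dosage_ld_matrix(b.maf, b.rho)
        return self._ld_cache[bi]

    def block_factor(self, bi: int) -> np.ndarray:
        """A factor F with F F' = R (eigenvalue-clipped) for MVN sampling."""
        if bi not in self._factor_cache:
            r = self.block_ld(bi)
            w, v = np.linalg.eigh(r)
            w = np.clip(w, 0.0, None)
            self._factor_cache[bi] = v * np.sqrt(w)
        return self._factor_cache[bi]


@dataclass
class PleiotropicLink:
    gene: str
    trait: str
    b_xy: float


@dataclass
class LinkageDecoy:
    gene: str
    trait: str
    r2: float  # latent-scale LD between protein-causal and trait-causal SNP
    effect: float = 0.055  # standardized trait effect at the decoy SNP


@dataclass
class TransLink:
    snp: str
    gene: str
    effect: float  # standardized effect of the SNP on abundance
    trait: str | None = None
    b_xy: float = 0.0  # mediation effect onto the trait


@dataclass
class AnnotationSpec:
    size: int
    target_fraction: float  # expected fraction of the target list inside the set


@dataclass
class PlantedTruth:
    traits: list[str]
    rg_matrix: pd.DataFrame
    pleiotropic_links: list[PleiotropicLink] = field(default_factory=list)
    linkage_decoys: list[LinkageDecoy] = field(default_factory=list)
    trans_links: list[TransLink] = field(default_factory=list)
    planted_ppi_fold: float = 1.0
    ppi_set_a: list[str] = field(default_factory=list)
    ppi_set_b: list[str] = field(default_factory=list)
    annotation_target: list[str] = field(default_factory=list)
    planted_annotation_overlap: dict[str, AnnotationSpec] = field(default_factory=dict)
    trait_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rg = self.rg_matrix.to_numpy(dtype=float)
        if rg.shape != (len(self.traits), len(self.traits)):
            raise ConfigurationError("rg matrix shape does not match traits")
        if self.traits:
            if not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
                raise ConfigurationError("rg matrix must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(rg).min() < -1e-8:
                raise ConfigurationError("rg matrix not positive semidefinite")
        for d in self.linkage_decoys:
            if not (0 <= d.r2 < 1):
                raise ConfigurationError("decoy r2 must be in [0, 1)")
        if self.planted_ppi_fold < 0:
            raise ConfigurationError("planted PPI fold must be >= 0")

    def validate_against(self, layout: GenomeLayout) -> None:
        genes = set(layout.genes["GENE"])
        snps = set(layout.snp_table["SNP"])
        for link in self.pleiotropic_links + self.linkage_decoys:
            if link.gene not in genes:
                raise ConfigurationError(f"unknown gene in truth: {link.gene}")
            if link.trait not in self.traits:
                raise ConfigurationError(f"unknown trait in truth: {link.trait}")
        for t in self.trans_links:
            if t.gene not in genes or t.snp not in snps:
                raise ConfigurationError(f"unknown gene/SNP in trans link: {t.gene}/{t.snp}")


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_blocks: int = 200
    snps_per_block: int = 100
    snp_spacing_bp: int = 10_000
    block_gap_bp: int = 200_000
    rho: float = 0.9
    n_chromosomes: int = 2
    n_genes: int = 200
    gene_span_bp: int = 10_000
    # cohorts
    n_gwas: int = 50_000
    n_panel: int = 500
    n_cohort: int = 722
    # molecular traits
    cis_h2: float = 0.3
    n_causal_cis: int = 1
    cis_window_bp: int = 500_000
    covariate_share: float = 0.1  # share of the non-genetic variance
    n_covariates: int = 2
    # GWAS polygenic architecture
    h2_trait: float = 0.4
    m_causal: int | None = None  # None -> every SNP is causal
    sample_overlap_corr: float = 0.0  # correlation of GWAS noise across traits
    # PPI
    ppi_background_q: float = 0.01
    ppi_universe_extra: int = 2800  # background symbols beyond the gene set
    ppi_physical_fraction: float = 0.8

    def __post_init__(self) -> None:
        if min(self.n_gwas, self.n_panel, self.n_cohort) < 2:
            raise ConfigurationError("all sample sizes must be >= 2")
        if not (0 <= self.cis_h2 <= 1) or not (0 <= self.h2_trait <= 1):
            raise ConfigurationError("heritabilities must lie in [0, 1]")
        if self.n_blocks <= 0 or self.snps_per_block <= 0:
            raise ConfigurationError("block sizes must be positive")
        if self.ppi_background_q < 0 or self.ppi_background_q > 1:
            raise ConfigurationError("PPI background probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# dosage-scale LD


def dosage_ld_matrix(maf: np.ndarray, rho: float, n_quad: int = 24) -> np.ndarray:
    """Population correlation matrix of 0/1/2 dosages under the copula model.

    Haplotype alleles are indicators I(u < Phi^-1(maf)) of latent AR(1)
    Gaussians with corr(u_i, u_j) = rho^|i-j|.  The dosage correlation is
    (Phi2(t_i, t_j; r) - p_i p_j) / sqrt(p_i q_i p_j q_j), with the
    bivariate-normal rectangle probability evaluated by Gauss-Legendre
    quadrature of dPhi2/dr (Plackett's identity).
    """
    maf = np.asarray(maf, dtype=float)
    m = len(maf)
    t = stats.norm.ppf(maf)
    lag = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    r_lat = np.power(float(rho), lag, where=lag > 0, out=np.ones_like(lag, dtype=float))
    np.fill_diagonal(r_lat, 1.0)
    if rho == 0:
        return np.eye(m)
    # integral_0^{r_ij} phi2(t_i, t_j; u) du via substitution u = r_ij * s
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    s = 0.5 * (nodes + 1.0)  # map to (0, 1)
    w = 0.5 * weights
    ti = t[:, None, None]
    tj = t[None, :, None]
    u = r_lat[:, :, None] * s[None, None, :]
    one_m_u2 = 1.0 - u * u
    dens = np.exp(-(ti * ti - 2.0 * u * ti * tj + tj * tj) / (2.0 * one_m_u2)) / (
        2.0 * np.pi * np.sqrt(one_m_u2)
    )
    cov = r_lat * np.einsum("ijk,k->ij", dens, w)
    sd = np.sqrt(maf * (1.0 - maf))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# genome + genotypes


def default_layout(config: SimulationConfig) -> GenomeLayout:
    """Blocks laid consecutively over ``n_chromosomes``, one gene per block
    (centered) until ``n_genes`` is exhausted."""
    rng = stage_rng(config.seed, "layout")
    blocks: list[LdBlock] = []
    per_chrom = int(np.ceil(config.n_blocks / config.n_chromosomes))
    block_span = config.snps_per_block * config.snp_spacing_bp
    gene_rows = []
    for bi in range(config.n_blocks):
        chrom = str(1 + bi // per_chrom)
        within = bi % per_chrom
        start = within * (block_span + config.block_gap_bp) + config.snp_spacing_bp
        positions = start + np.arange(config.snps_per_block) * config.snp_spacing_bp
        maf = rng.uniform(0.05, 0.5, size=config.snps_per_block)
        blocks.append(LdBlock(chrom=chrom, positions=positions, maf=maf, rho=config.rho))
        if len(gene_rows) < config.n_genes:
            center = int(positions[config.snps_per_block // 2])
            gene_rows.append(
                (f"G{len(gene_rows):04d}", chrom, center - config.gene_span_bp // 2, center + config.gene_span_bp // 2)
            )
    genes = pd.DataFrame(gene_rows, columns=["GENE", "CHR", "START", "END"])
    return GenomeLayout(blocks=blocks, genes=genes)


def _sample_dosages(layout: GenomeLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n individuals' dosages: two latent AR(1) haplotypes thresholded
    at the MAF quantile; dosage counts the minor (A1) allele."""
    out = np.empty((n, layout.n_snps), dtype=np.int8)
    col = 0
    for b in layout.blocks:
        m = b.n_snps
        t = stats.norm.ppf(b.maf)
        hap = np.empty((2 * n, m))
        hap[:, 0] = rng.standard_normal(2 * n)
        if m > 1:
            innov = rng.standard_normal((2 * n, m - 1)) * np.sqrt(1.0 - b.rho**2)
            for j in range(1, m):
                hap[:, j] = b.rho * hap[:, j - 1] + innov[:, j - 1]
        alleles = (hap < t).astype(np.int8)  # bool + bool would be logical OR
        out[:, col : col + m] = alleles[:n] + alleles[n:]
        col += m
    return out


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]  # never strand-ambiguous


def simulate_genome(config: SimulationConfig, layout: GenomeLayout | None = None):
    """Build the genome layout plus reference-panel and cohort genotypes."""
    if layout is None:
        layout = default_layout(config)
    rng_alleles = stage_rng(config.seed, "alleles")
    pair_idx = rng_alleles.integers(0, len(_ALLELE_PAIRS), size=layout.n_snps)
    snps = layout.snp_table[["SNP", "CHR", "BP"]].copy()
    snps["A1"] = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    snps["A2"] = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    panel = GenotypePanel(
        snps=snps.copy(),
        dosages=_sample_dosages(layout, config.n_panel, stage_rng(config.seed, "panel-genotypes")),
        samples=[f"P{i:04d}" for i in range(config.n_panel)],
    )
    cohort = GenotypePanel(
        snps=snps.copy(),
        dosages=_sample_dosages(layout, config.n_cohort, stage_rng(config.seed, "cohort-genotypes")),
        samples=[f"C{i:04d}" for i in range(config.n_cohort)],
    )
    return layout, panel, cohort


# ---------------------------------------------------------------------------
# shared cis architecture


def cis_snp_indices(layout: GenomeLayout, gene: str, window_bp: int = 500_000) -> np.ndarray:
    row = layout.genes.loc[layout.genes["GENE"] == gene]
    if row.empty:
        raise KeyError(f"unknown gene {gene}")
    row = row.iloc[0]
    tab = layout.snp_table
    mask = (
        (tab["CHR"] == row["CHR"])
        & (tab["BP"] >= row["START"] - window_bp)
        & (tab["BP"] <= row["END"] + window_bp)
    )
    return np.flatnonzero(mask.to_numpy())


def cis_architecture(layout: GenomeLayout, config: SimulationConfig, gene: str):
    """Deterministic causal cis SNPs and standardized effect sizes for a gene.

    Shared between the molecular-cohort and summary-level GWAS stages so
    mediated trait effects line up with the cohort's pQTL effects.  Effects
    are scaled so the population genetic variance beta' R beta equals the
    target cis h².
    """
    idx = cis_snp_indices(layout, gene, config.cis_window_bp)
    if len(idx) == 0:
        raise ConfigurationError(f"gene {gene} has no cis SNPs")
    rng = stage_rng(config.seed, f"cis-arch:{gene}")
    k = min(config.n_causal_cis, len(idx))
    # keep causal SNPs off the block edges so LD "flanks" exist for HEIDI
    interior = idx[len(idx) // 4 : -len(idx) // 4] if len(idx) >= 8 else idx
    chosen = np.sort(rng.choice(interior, size=k, replace=False))
    raw = rng.standard_normal(k)
    if config.cis_h2 == 0:
        return chosen, np.zeros(k)
    tab = layout.snp_table.iloc[chosen]
    bi = int(tab["BLOCK"].iloc[0])
    local = tab["IDX"].to_numpy()
    r_sub = layout.block_ld(bi)[np.ix_(local, local)] if (tab["BLOCK"] == bi).all() else np.eye(k)
    scale = np.sqrt(config.cis_h2 / float(raw @ r_sub @ raw))
    return chosen, raw * scale


# ---------------------------------------------------------------------------
# molecular cohort


def simulate_molecular_traits(layout: GenomeLayout, truth: PlantedTruth, config: SimulationConfig, cohort: GenotypePanel):
    """Abundance (n_cohort x genes, z-scaled) and covariate tables.

    abundance = cis genetic value + trans genetic value + covariate effect
    + Gaussian noise, with each component rescaled to its realized target
    variance so realized cis h² equals the configured target exactly.
    """
    if config.cis_h2 > 1:
        raise ConfigurationError("target cis h² exceeds 1")
    rng = stage_rng(config.seed, "molecular-noise")
    x = cohort.standardized()
    n = cohort.n_samples
    cov_rng = stage_rng(config.seed, "covariates")
    covs = cov_rng.standard_normal((n, config.n_covariates))
    trans_by_gene: dict[str, list[TransLink]] = {}
    for t in truth.trans_links:
        trans_by_gene.setdefault(t.gene, []).append(t)
    snp_pos = pd.Index(cohort.snps["SNP"])
    cols = {}
    for gene in layout.genes["GENE"]:
        idx, beta = cis_architecture(layout, config, gene)
        h2 = config.cis_h2
        g = x[:, idx] @ beta if h2 > 0 else np.zeros(n)
        comp = _scaled(g, h2)
        var_left = 1.0 - h2
        for t in trans_by_gene.get(gene, []):
            j = snp_pos.get_loc(t.snp)
            tv = t.effect**2
            comp = comp + _scaled(x[:, j] * t.effect, tv)
            var_left -= tv
        if var_left < 0:
            raise ConfigurationError(f"variance budget exceeded for {gene}")
        var_cov = config.covariate_share * var_left
        gamma = cov_rng.standard_normal(config.n_covariates)
        comp = comp + _scaled(covs @ gamma, var_cov)
        comp = comp + _scaled(rng.standard_normal(n), var_left - var_cov)
        sd = comp.std()
        cols[gene] = comp / sd if sd > 0 else comp
    abundance = pd.DataFrame(cols, index=cohort.samples)
    covariates = pd.DataFrame(covs, index=cohort.samples, columns=[f"COV{i+1}" for i in range(config.n_covariates)])
    return abundance, covariates


def _scaled(v: np.ndarray, target_var: float) -> np.ndarray:
    if target_var <= 0:
        return np.zeros_like(v)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return v * np.sqrt(target_var) / sd


# ---------------------------------------------------------------------------
# GWAS summary statistics


def _decoy_snp(layout: GenomeLayout, config: SimulationConfig, gene: str, r2: float) -> tuple[int, int]:
    """Pick the trait-causal SNP for a linkage decoy: same block as the
    protein-causal SNP, at the lag whose latent r² is closest to target."""
    idx, _ = cis_architecture(layout, config, gene)
    j = int(idx[0])
    row = layout.snp_table.iloc[j]
    bi, local = int(row["BLOCK"]), int(row["IDX"])
    if r2 <= 0:
        raise ConfigurationError("decoy r2 must be positive to pick a distinct SNP")
    lag = max(1, round(np.log(r2) / (2.0 * np.log(config.rho))))
    b = layout.blocks[bi]
    local_t = local + lag if local + lag < b.n_snps else local - lag
    return j, j + (local_t - local)


def _joint_effects(layout: GenomeLayout, truth: PlantedTruth, config: SimulationConfig) -> pd.DataFrame:
    """Per-SNP standardized effect sizes for every trait (SNPs x traits)."""
    n_snps, traits = layout.n_snps, truth.traits
    m = config.m_causal or n_snps
    rng = stage_rng(config.seed, "polygenic-effects")
    chol = np.linalg.cholesky(truth.rg_matrix.to_numpy(dtype=float) + 1e-10 * np.eye(len(traits)))
    eff = np.zeros((n_snps, len(traits)))
    if config.h2_trait > 0 and m > 0:
        g = rng.standard_normal((m, len(traits))) @ chol.T * np.sqrt(config.h2_trait / m)
        if m >= n_snps:
            sites = np.arange(n_snps)
        else:
            sites = np.sort(stage_rng(config.seed, "polygenic-sites").choice(n_snps, size=m, replace=False))
        eff[sites] += g
    ti = {t: k for k, t in enumerate(traits)}
    for link in truth.pleiotropic_links:
        idx, beta = cis_architecture(layout, config, link.gene)
        eff[idx, ti[link.trait]] += link.b_xy * beta
    for decoy in truth.linkage_decoys:
        _, j_trait = _decoy_snp(layout, config, decoy.gene, decoy.r2)
        eff[j_trait, ti[decoy.trait]] += decoy.effect
    snp_pos = pd.Index(layout.snp_table["SNP"])
    for t in truth.trans_links:
        if t.trait is not None and t.b_xy != 0:
            eff[snp_pos.get_loc(t.snp), ti[t.trait]] += t.b_xy * t.effect
    return pd.DataFrame(eff, columns=traits)


def simulate_gwas(
    layout: GenomeLayout,
    truth: PlantedTruth,
    config: SimulationConfig,
    trait: str,
    panel_snps: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Summary statistics for one trait (all traits are drawn jointly so any
    single trait is reproducible in isolation)."""
    if trait not in truth.traits:
        raise KeyError(f"trait {trait} absent from planted truth")
    zs = simulate_all_gwas(layout, truth, config, panel_snps)
    return zs[trait]


def simulate_all_gwas(layout, truth, config, panel_snps=None) -> dict[str, pd.DataFrame]:
    if not truth.traits:
        return {}
    eff = _joint_effects(layout, truth, config).to_numpy()
    n_traits = len(truth.traits)
    omega = np.full((n_traits, n_traits), config.sample_overlap_corr)
    np.fill_diagonal(omega, 1.0)
    chol_noise = np.linalg.cholesky(omega + 1e-12 * np.eye(n_traits))
    rng = stage_rng(config.seed, "gwas-noise")
    z = np.empty_like(eff)
    for bi, sl in enumerate(layout.block_slices()):
        r = layout.block_ld(bi)
        f = layout.block_factor(bi)
        mean = np.sqrt(config.n_gwas) * (r @ eff[sl])
        noise = f @ (rng.standard_normal((r.shape[0], n_traits)) @ chol_noise.T)
        z[sl] = mean + noise
    if panel_snps is None:
        base = layout.snp_table[["SNP", "CHR", "BP", "MAF"]].copy()
        base["A1"], base["A2"] = "A", "G"
    else:
        base = panel_snps[["SNP", "CHR", "BP", "A1", "A2"]].merge(
            layout.snp_table[["SNP", "MAF"]], on="SNP"
        )
    out = {}
    for k, t in enumerate(truth.traits):
        df = base.copy()
        df["Z"] = z[:, k]
        df["N"] = config.n_gwas
        df["FREQ"] = df.pop("MAF")
        out[t] = df[["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "FREQ"]]
    return out


def simulate_region_summary(
    seed: int,
    n_snps: int = 60,
    rho: float = 0.9,
    n_gwas: int = 50_000,
    n_pqtl: int = 722,
    cis_h2: float = 0.3,
    b_xy: float = 0.1,
    causal_index: int | None = None,
    trait_causal_index: int | None = None,
    trait_effect: float | None = None,
):
    """Summary statistics for a single cis region, for mediation experiments.

    The protein has one causal SNP (effect sqrt(cis_h2) standardized).  Under
    pleiotropy/causality the trait effect sits on the same SNP (b_xy times
    the protein effect); under linkage a distinct ``trait_causal_index``
    carries ``trait_effect`` instead.  Returns (gwas_df, pqtl_df, ld_df)
    with columns SNP/BETA/SE/P on the standardized scale.
    """
    rng = stage_rng(seed, "region")
    maf = rng.uniform(0.05, 0.5, size=n_snps)
    r = dosage_ld_matrix(maf, rho)
    w, v = np.linalg.eigh(r)
    f = v * np.sqrt(np.clip(w, 0, None))
    j_p = n_snps // 2 if causal_index is None else causal_index
    a_p = np.zeros(n_snps)
    a_p[j_p] = np.sqrt(cis_h2)
    a_g = np.zeros(n_snps)
    if trait_causal_index is None:
        a_g[j_p] = b_xy * a_p[j_p]
    else:
        a_g[trait_causal_index] = trait_effect if trait_effect is not None else b_xy * np.sqrt(cis_h2)
    snps = [f"s{k:03d}" for k in range(n_snps)]
    out = []
    for a, n in ((a_g, n_gwas), (a_p, n_pqtl)):
        bhat = r @ a + f @ rng.standard_normal(n_snps) / np.sqrt(n)
        se = np.full(n_snps, 1.0 / np.sqrt(n))
        z = bhat / se
        out.append(
            pd.DataFrame({"SNP": snps, "BETA": bhat, "SE": se,
                          "P": 2.0 * stats.norm.sf(np.abs(z))})
        )
    ld = pd.DataFrame(r, index=snps, columns=snps)
    return out[0], out[1], ld


# ---------------------------------------------------------------------------
# PPI network + annotations


def simulate_ppi(truth: PlantedTruth, config: SimulationConfig, universe: list[str]) -> pd.DataFrame:
    """Edge table with Bernoulli(q) background and Bernoulli(q*fold) edges
    between the designated set-A x set-B pairs; no self-loops or duplicates."""
    if truth.planted_ppi_fold < 0:
        raise ConfigurationError("planted fold must be >= 0")
    missing = (set(truth.ppi_set_a) | set(truth.ppi_set_b)) - set(universe)
    if missing:
        raise ConfigurationError(f"PPI universe lacks set members, e.g. {sorted(missing)[:3]}")
    rng = stage_rng(config.seed, "ppi")
    n = len(universe)
    node_index = {s: i for i, s in enumerate(universe)}
    a_idx = np.array([node_index[s] for s in truth.ppi_set_a], dtype=np.int64)
    b_idx = np.array([node_index[s] for s in truth.ppi_set_b], dtype=np.int64)
    in_a = np.zeros(n, bool)
    in_a[a_idx] = True
    in_b = np.zeros(n, bool)
    in_b[b_idx] = True
    q = config.ppi_background_q
    n_pairs = n * (n - 1) // 2
    k_bg = rng.binomial(n_pairs, q) if q > 0 else 0
    chosen = rng.choice(n_pairs, size=k_bg, replace=False) if k_bg else np.array([], dtype=np.int64)
    i, j = _pair_decode(chosen, n)
    cross = (in_a[i] & in_b[j]) | (in_b[i] & in_a[j])
    i, j = i[~cross], j[~cross]
    # explicit draws over the inter-set pairs at q * fold
    ai, bj = np.meshgrid(a_idx, b_idx, indexing="ij")
    ai, bj = ai.ravel(), bj.ravel()
    keep = ai != bj
    ai, bj = ai[keep], bj[keep]
    lo, hi = np.minimum(ai, bj), np.maximum(ai, bj)
    dedup = pd.unique(lo * n + hi)
    lo, hi = dedup // n, dedup % n
    hit = rng.random(len(lo)) < min(1.0, q * truth.planted_ppi_fold)
    i = np.concatenate([i, lo[hit]])
    j = np.concatenate([j, hi[hit]])
    ev_pool = rng.random(len(i))
    phys = rng.integers(0, len(PHYSICAL_EVIDENCE), size=len(i))
    nonphys = rng.integers(0, len(NONPHYSICAL_EVIDENCE), size=len(i))
    evidence = np.where(
        ev_pool < config.ppi_physical_fraction,
        np.array(PHYSICAL_EVIDENCE)[phys],
        np.array(NONPHYSICAL_EVIDENCE)[nonphys],
    )
    uni = np.array(universe)
    df = pd.DataFrame({"SYMBOL_A": uni[i], "SYMBOL_B": uni[j], "EVIDENCE_TYPE": evidence})
    return df.sort_values(["SYMBOL_A", "SYMBOL_B"], ignore_index=True)


def _pair_decode(code: np.ndarray, n: int):
    """Decode linear indices of the upper triangle (i<j) of an n x n grid."""
    code = np.asarray(code, dtype=np.int64)
    i = (n - 2 - np.floor(np.sqrt(-8.0 * code + 4.0 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
    j = code + i + 1 - (i * (2 * n - i - 1)) // 2
    return i, j


def simulate_annotations(truth: PlantedTruth, config: SimulationConfig, universe: list[str]) -> dict[str, list[str]]:
    """GMT-style sets honoring the planted in-target fractions in expectation."""
    rng = stage_rng(config.seed, "annotations")
    target = [g for g in truth.annotation_target if g in set(universe)]
    rest = [g for g in universe if g not in set(target)]
    sets: dict[str, list[str]] = {}
    for name, spec in truth.planted_annotation_overlap.items():
        if spec.size > len(universe):
            raise ConfigurationError(f"annotation set {name} larger than universe")
        hit = rng.random(len(target)) < spec.target_fraction
        members = [g for g, h in zip(target, hit) if h]
        n_fill = spec.size - len(members)
        if n_fill < 0:
            members = members[: spec.size]
            n_fill = 0
        fill = rng.choice(len(rest), size=min(n_fill, len(rest)), replace=False)
        members += [rest[k] for k in sorted(fill)]
        sets[name] = sorted(members)
    return sets


# ---------------------------------------------------------------------------
# study assembly


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    layout: GenomeLayout
    truth: PlantedTruth
    panel: GenotypePanel
    cohort: GenotypePanel
    abundance: pd.DataFrame
    covariates: pd.DataFrame
    sumstats: dict[str, pd.DataFrame]
    ppi: pd.DataFrame
    ppi_universe: list[str]
    annotations: dict[str, list[str]]


def default_truth(config: SimulationConfig, layout: GenomeLayout) -> PlantedTruth:
    """The stated default world: 5 traits in 3 groups, rg 0.5 within group and
    0.2 between, 10 pleiotropic genes, 5 linkage decoys (r²=0.7), 3 trans
    links, a PPI excess of 2.5x between two causal sets sized like the real
    study (404/43 with 13 shared)."""
    traits = ["T1", "T2", "T3", "T4", "T5"]
    groups = {"T1": "psychiatric", "T2": "psychiatric", "T3": "neurodegenerative", "T4": "neurodegenerative", "T5": "brain_structure"}
    rg = np.full((5, 5), 0.2)
    for a in range(5):
        for b in range(5):
            if groups[traits[a]] == groups[traits[b]]:
                rg[a, b] = 0.5
    np.fill_diagonal(rg, 1.0)
    rg_df = pd.DataFrame(rg, index=traits, columns=traits)
    genes = list(layout.genes["GENE"])
    plei_map = [
        (0, ["T1", "T3"]), (1, ["T1", "T2"]), (2, ["T2"]), (3, ["T1"]), (4, ["T3", "T4"]),
        (5, ["T4"]), (6, ["T5"]), (7, ["T1", "T4"]), (8, ["T3"]), (9, ["T5", "T2"]),
    ]
    links = [PleiotropicLink(genes[gi], t, 0.1) for gi, ts in plei_map if gi < len(genes) for t in ts]
    decoys = [
        LinkageDecoy(genes[10 + k], t, 0.7)
        for k, t in enumerate(["T1", "T2", "T3", "T4", "T1"])
        if 10 + k < len(genes)
    ]
    snp_tab = layout.snp_table
    trans = []
    for k, (gi, t) in enumerate(zip((15, 16, 17), ("T1", "T3", "T4"))):
        if gi >= len(genes):
            continue
        gene_chr = layout.genes.iloc[gi]["CHR"]
        other = snp_tab[snp_tab["CHR"] != gene_chr]
        if other.empty:
            continue
        snp = other.iloc[(len(other) // 4) * (k + 1)]["SNP"]
        trans.append(TransLink(snp=snp, gene=genes[gi], effect=0.4, trait=t, b_xy=0.1))
    bg = [f"BG{k:04d}" for k in range(config.ppi_universe_extra)]
    universe = genes + bg
    psych_genes = sorted({l.gene for l in links if groups[l.trait] == "psychiatric"})
    neuro_genes = sorted({l.gene for l in links if groups[l.trait] == "neurodegenerative"})
    shared = sorted(set(psych_genes) & set(neuro_genes))
    # set sizes mirror the real study (404/43 with 13 shared), clamped so
    # small toy universes still produce valid sets
    n_a = min(404, max(len(psych_genes) + 1, len(universe) // 2))
    n_b = min(43, max(len(neuro_genes) + 1, len(universe) // 10))
    n_shared = max(len(shared), min(13, n_a, n_b))
    pool = iter([s for s in universe if s not in set(psych_genes) | set(neuro_genes)])
    extra_shared = [next(pool) for _ in range(n_shared - len(shared))]
    set_a = psych_genes + extra_shared
    set_b = neuro_genes + extra_shared
    set_a += [next(pool) for _ in range(n_a - len(set_a))]
    set_b += [next(pool) for _ in range(n_b - len(set_b))]
    target = sorted(set(set_a[: min(100, n_a)]) | set(set_b[: min(18, n_b)]))  # the "interacting" list
    return PlantedTruth(
        traits=traits,
        rg_matrix=rg_df,
        pleiotropic_links=links,
        linkage_decoys=decoys,
        trans_links=trans,
        planted_ppi_fold=2.5,
        ppi_set_a=set_a,
        ppi_set_b=set_b,
        annotation_target=target,
        planted_annotation_overlap={
            "synaptic_like": AnnotationSpec(size=min(1000, len(universe) // 3), target_fraction=0.8),
            "mito_like": AnnotationSpec(size=min(150, len(universe) // 20), target_fraction=0.2),
        },
        trait_groups=groups,
    )


def simulate_study(config: SimulationConfig, truth: PlantedTruth | None = None) -> SyntheticStudy:
    layout, panel, cohort = simulate_genome(config)
    if truth is None:
        truth = default_truth(config, layout)
    truth.validate_against(layout)
    abundance, covariates = simulate_molecular_traits(layout, truth, config, cohort)
    sumstats = simulate_all_gwas(layout, truth, config, panel.snps)
    universe = list(layout.genes["GENE"]) + [f"BG{k:04d}" for k in range(config.ppi_universe_extra)]
    ppi = simulate_ppi(truth, config, universe)
    annotations = simulate_annotations(truth, config, universe)
    return SyntheticStudy(
        config=config, layout=layout, truth=truth, panel=panel, cohort=cohort,
        abundance=abundance, covariates=covariates, sumstats=sumstats,
        ppi=ppi, ppi_universe=universe, annotations=annotations,
    )


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, str]:
    """Write every pipeline input plus the truth manifest; returns a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _reg(key, path):
        manifest[key] = str(path)
        return path

    write_vcf(study.panel, _reg("panel_vcf", directory / "panel.vcf"))
    write_vcf(study.cohort, _reg("cohort_vcf", directory / "cohort.vcf"))
    for trait, ss in study.sumstats.items():
        write_sumstats(ss, _reg(f"sumstats:{trait}", directory / f"sumstats_{trait}.tsv"))
    write_table(study.abundance, _reg("abundance", directory / "abundance.tsv"), index=True)
    write_table(study.covariates, _reg("covariates", directory / "covariates.tsv"), index=True)
    write_table(study.layout.genes, _reg("genes", directory / "genes.tsv"))
    write_table(study.ppi, _reg("ppi", directory / "ppi.tsv"))
    write_gmt(study.annotations, _reg("annotations", directory / "annotations.gmt"))
    truth = study.truth
    write_json(
        {
            "traits": truth.traits,
            "trait_groups": truth.trait_groups,
            "rg_matrix": truth.rg_matrix.to_numpy().tolist(),
            "pleiotropic_links": [vars(l) for l in truth.pleiotropic_links],
            "linkage_decoys": [vars(d) for d in truth.linkage_decoys],
            "trans_links": [vars(t) for t in truth.trans_links],
            "planted_ppi_fold": truth.planted_ppi_fold,
            "ppi_set_a": truth.ppi_set_a,
            "ppi_set_b": truth.ppi_set_b,
            "annotation_target": truth.annotation_target,
            "seed": study.config.seed,
        },
        _reg("truth", directory / "truth.json"),
    )
    write_json(manifest, directory / "manifest.json")
    return manifest
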
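# pleioscan

Multi-trait integration of GWAS summary statistics with brain molecular QTL
data. Given summary statistics for a collection of psychiatric,
neurodegenerative and brain-structure traits, a reference LD panel, and a
molecular cohort (genotypes plus protein or mRNA abundance), `pleioscan`

1. estimates pairwise **genetic correlations** by LD score regression,
2. screens genes for **cis heritability**, trains predictive cis weight
   models, and computes **PWAS/TWAS** association z-scores,
3. tests mediation with **SMR** and filters linkage with **HEIDI**, and
   colocalization with **COLOC** posteriors,
4. maps **cis and trans pQTLs** and applies explicit decision rules to call
   genes *consistent with a causal role* for each trait,
5. tabulates **sharing** of causal genes within and between trait groups,
   and tests for an excess of **physical protein-protein interactions**
   between two causal-gene sets with a constrained bootstrap, plus
   fold/hypergeometric enrichment against annotation sets (GMT).

It ships a first-class synthetic-study generator with planted truth
(block-LD genotypes, polygenic trait pairs with target genetic
correlations, cis-heritable molecular traits, mediated signals versus
linkage decoys, trans links, PPI networks with a planted inter-set edge
excess), so the entire pipeline is testable end to end without any external
download. It is aimed at statistical geneticists who want a transparent,
desk-scale reimplementation of this integration strategy rather than a
wrapper around the original tools.

## The statistics at the core

- **LDSC**: regression of χ² on `N·ℓ_j/M` with free intercept; cross-trait
  `z₁z₂` on `√(N₁N₂)·ℓ_j/M`, rg = slope / √(h₁²h₂²); SNPs with χ² > 80
  removed; block-jackknife standard errors.
- **PWAS/TWAS**: `z = w'Z / √(w'Rw)` over trained cis weights `w` (best of
  top-SNP / ridge / lasso / elastic net by 5-fold CV R²), panel LD `R`.
- **SMR**: `T_SMR = z_g²z_p²/(z_g²+z_p²) ~ χ²₁`; **HEIDI**: heterogeneity
  of `b_xy = β_GWAS/β_pQTL` across LD-linked instruments, referred to a
  weighted sum of χ²₁ (Ruben series / Imhof / saddlepoint / Monte Carlo).
- **COLOC**: Wakefield log-ABFs, five-hypothesis enumeration in log space,
  decision at PP4 > 0.5.
- **Causal criteria** — cis: PWAS FDR p < 0.05 AND (SMR p < 0.05 with HEIDI
  p > 0.05, or PP4 > 0.5); trans: pQTL p < 5×10⁻⁸ beyond 500 kb, trans-SMR
  under Bonferroni 0.05/#trans-pQTLs, HEIDI p > 0.05.
- **PPI bootstrap**: redraw the two sets (sizes and shared count preserved)
  from the network universe; `p = (1 + Σ I(s_i ≥ s₀))/(N+1)` exactly.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

The fold-enrichment arithmetic on the published counts — 102 synaptic
proteins among 118 interacting causal proteins, a 7,907-protein synaptic
set, a 20,338-protein background:

```python
from pleioscan.ppi import fold_enrichment_counts
res = fold_enrichment_counts(k=102, n=118, K=7907, N_bg=20338)
print(f"fold = {res.fold:.2f}, hypergeometric p = {res.hypergeom_p:.2e}")
```

```
fold = 2.22, hypergeometric p = 9.99e-27
```

i.e. the target list is 2.2-fold enriched for synaptic proteins, far beyond
chance. A small end-to-end synthetic study (2,000 SNPs, 40 genes, 5 traits
in 3 groups, planted pleiotropic genes / linkage decoys / trans links):

```python
from pleioscan.simulate import SimulationConfig, simulate_study
from pleioscan.pipeline import bundle_from_simulation, run_study

cfg = SimulationConfig(seed=7, n_blocks=40, snps_per_block=50, n_genes=40,
                       n_panel=400, n_cohort=400, ppi_universe_extra=1000)
study = simulate_study(cfg)
result = run_study(bundle_from_simulation(study), seed=7, with_rg=False)

calls = result.causal_calls
print(f"{len(calls)} causal calls "
      f"({(calls['MODE'] == 'cis').sum()} cis, {(calls['MODE'] == 'trans').sum()} trans)")
print(calls[["GENE", "TRAIT", "MODE", "ROUTE"]].head(6).to_string(index=False))
```

```
18 causal calls (16 cis, 2 trans)
 GENE TRAIT MODE     ROUTE
G0000    T1  cis     COLOC
G0001    T1  cis     COLOC
G0002    T2  cis      BOTH
G0004    T1  cis SMR_HEIDI
G0005    T4  cis     COLOC
G0007    T4  cis      BOTH
```

Genes `G0000`–`G0009` carry the planted mediated effects, and the calls
recover them; the `ROUTE` column records which evidence branch fired
(SMR+HEIDI, COLOC, or both). `result.sharing.per_trait` holds the
per-trait sharing table (percent of each trait's causal genes shared with
each trait group; dashes where a trait has no calls), and
`result.extras["ppi_bootstrap"]` the network excess test.

The same pipeline runs from the shell on a study directory:

```bash
pleioscan simulate --config cfg.yaml --out study/
pleioscan run --study study/ --out results/ --seed 1
pleioscan ldsc --study study/ --out ldsc/
pleioscan ppi --ppi study/ppi.tsv --set-a a.txt --set-b b.txt --iters 10000 --seed 7 --out ppi/
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic study (20k SNPs,
5 traits, 200 genes, planted truth) from the given seed, runs the full
pipeline — genetic correlations, heritability screen, weights, PWAS,
SMR/HEIDI, COLOC, cis and trans causal calls, sharing tabulation, PPI
bootstrap — prints a run summary, and writes the acceptance JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
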
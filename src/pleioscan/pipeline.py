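"""End-to-end orchestration: from study inputs to causal calls, sharing
tables and network enrichment.

Each stage is the corresponding module's public surface; this file only
wires them together and handles bookkeeping (which gene x trait pairs reach
which stage).  SMR/COLOC run only for XWAS-significant pairs, mirroring the
design in which mediation tests follow the association screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import coloc as coloc_mod
from . import ldsc as ldsc_mod
from . import ppi as ppi_mod
from . import qtl as qtl_mod
from . import smr as smr_mod
from . import xwas as xwas_mod
from ._rng import stage_seed
from .calls import PipelineThresholds
from .io import (
    GenotypePanel,
    read_gene_coords,
    read_gmt,
    read_json,
    read_ppi,
    read_sumstats,
    read_table,
    read_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class StudyBundle:
    """The pipeline's input container (what a study directory holds)."""

    panel: GenotypePanel
    cohort: GenotypePanel
    abundance: pd.DataFrame
    covariates: pd.DataFrame
    sumstats: dict[str, pd.DataFrame]
    genes: pd.DataFrame
    groups: dict[str, str]
    ppi: pd.DataFrame | None = None
    annotations: dict[str, list[str]] | None = None
    ppi_universe: list[str] | None = None


def load_study(directory: str | Path) -> StudyBundle:
    """Read a study directory written by ``simulate.write_study``."""
    d = Path(directory)
    manifest = read_json(d / "manifest.json")
    truth = read_json(manifest["truth"])
    sumstats = {
        key.split(":", 1)[1]: read_sumstats(path)
        for key, path in manifest.items()
        if key.startswith("sumstats:")
    }
    return StudyBundle(
        panel=read_vcf(manifest["panel_vcf"]),
        cohort=read_vcf(manifest["cohort_vcf"]),
        abundance=read_table(manifest["abundance"], index_col=0),
        covariates=read_table(manifest["covariates"], index_col=0),
        sumstats=sumstats,
        genes=read_gene_coords(manifest["genes"]),
        groups=truth["trait_groups"],
        ppi=read_ppi(manifest["ppi"]) if "ppi" in manifest else None,
        annotations=read_gmt(manifest["annotations"]) if "annotations" in manifest else None,
    )


def bundle_from_simulation(study) -> StudyBundle:
    """Adapter from a ``simulate.SyntheticStudy`` (no disk round trip)."""
    return StudyBundle(
        panel=study.panel,
        cohort=study.cohort,
        abundance=study.abundance,
        covariates=study.covariates,
        sumstats=study.sumstats,
        genes=study.layout.genes,
        groups=study.truth.trait_groups,
        ppi=study.ppi,
        annotations=study.annotations,
        ppi_universe=study.ppi_universe,
    )


@dataclass
class PipelineResult:
    ld_scores: pd.DataFrame
    rg_table: pd.DataFrame | None
    heritability: pd.DataFrame
    weights: list
    xwas: pd.DataFrame
    cis_pqtl: pd.DataFrame
    smr: pd.DataFrame
    coloc: pd.DataFrame
    trans_pqtl: pd.DataFrame | None
    trans_smr: pd.DataFrame | None
    causal_calls: pd.DataFrame
    sharing: calls_mod.SharingSummary | None
    extras: dict = field(default_factory=dict)


def _panel_ld(panel: GenotypePanel, snp_ids) -> pd.DataFrame:
    idx = panel.index_of(snp_ids)
    x = panel.standardized()[:, idx]
    r = x.T @ x / panel.n_samples
    ids = list(snp_ids)
    return pd.DataFrame(r, index=ids, columns=ids)


def full_covariates(bundle: StudyBundle, n_pcs: int = 10, seed: int = 0) -> pd.DataFrame:
    pcs = qtl_mod.genotype_pcs(bundle.cohort, n_components=n_pcs, seed=stage_seed(seed, "pcs") % (2**31))
    return pd.concat([bundle.covariates, pcs], axis=1)


def run_rg_matrix(bundle: StudyBundle, ld_scores: pd.DataFrame) -> pd.DataFrame:
    traits = list(bundle.sumstats)
    filtered = {t: ldsc_mod.filter_large_effects(bundle.sumstats[t]) for t in traits}
    ests = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1 :]:
            ests.append(
                ldsc_mod.estimate_rg(filtered[t1], filtered[t2], ld_scores, trait1=t1, trait2=t2)
            )
    return ldsc_mod.rg_matrix_fdr(ests)


def run_study(
    bundle: StudyBundle,
    thresholds: PipelineThresholds | None = None,
    seed: int = 0,
    n_pcs: int = 10,
    with_rg: bool = True,
    with_trans: bool = True,
    with_ppi: bool = True,
    ppi_iterations: int = 1000,
) -> PipelineResult:
    thresholds = thresholds or PipelineThresholds()
    traits = list(bundle.sumstats)
    ld_scores = ldsc_mod.compute_ld_scores(bundle.panel)
    rg_table = run_rg_matrix(bundle, ld_scores) if with_rg and len(traits) > 1 else None

    covariates = full_covariates(bundle, n_pcs=n_pcs, seed=seed)

    # heritability screen
    herit_records = []
    for gene in bundle.genes["GENE"]:
        try:
            herit_records.append(
                qtl_mod.estimate_cis_h2(bundle.cohort, bundle.abundance[gene], covariates, gene, bundle.genes)
            )
        except ValueError as exc:
            log.info("heritability: %s skipped (%s)", gene, exc)
    heritability = pd.DataFrame([vars(h) for h in herit_records])
    heritable = heritability.loc[heritability["heritable"], "gene"].tolist()

    # weights for heritable genes
    weights = []
    h2_by_gene = heritability.set_index("gene")["h2_clamped"]
    for gene in heritable:
        ws = qtl_mod.fit_weights(
            bundle.cohort, bundle.abundance[gene], covariates, gene, bundle.genes,
            h2_guess=float(h2_by_gene[gene]), seed=stage_seed(seed, f"cv:{gene}") % (2**31),
        )
        if ws is not None:
            weights.append(ws)

    # XWAS per trait
    xwas_frames = []
    for t in traits:
        xwas_frames.append(xwas_mod.run_xwas(weights, bundle.sumstats[t], bundle.panel, trait=t, fdr=thresholds.xwas_fdr))
    xwas = pd.concat(xwas_frames, ignore_index=True)

    # cis pQTLs for genes significant in any trait
    sig_pairs = xwas.loc[xwas["SIGNIFICANT"], ["GENE", "TRAIT"]]
    sig_genes = sorted(set(sig_pairs["GENE"]))
    cis_pqtl = (
        qtl_mod.cis_pqtl_scan(
            bundle.cohort, bundle.abundance[sig_genes], covariates,
            bundle.genes.loc[bundle.genes["GENE"].isin(sig_genes)],
        )
        if sig_genes
        else pd.DataFrame(columns=["SNP", "GENE", "BETA", "SE", "P", "DISTANCE", "BP", "TRANS", "LEAD"])
    )

    # SMR + HEIDI + COLOC per significant gene x trait
    smr_rows, coloc_rows, cis_calls = [], [], []
    ld_cache: dict[str, pd.DataFrame] = {}
    for gene in sig_genes:
        gp = cis_pqtl.loc[cis_pqtl["GENE"] == gene]
        lead = gp.loc[gp["LEAD"]].iloc[0]
        if gene not in ld_cache:
            ld_cache[gene] = _panel_ld(bundle.panel, gp["SNP"].tolist())
        ld_r = ld_cache[gene]
        z_pqtl = float(lead["BETA"] / lead["SE"])
        for t in sig_pairs.loc[sig_pairs["GENE"] == gene, "TRAIT"]:
            ss = bundle.sumstats[t].set_index("SNP")
            shared = [s for s in gp["SNP"] if s in ss.index]
            gps = gp.set_index("SNP").loc[shared].reset_index()
            zs = ss.loc[shared]
            if lead["SNP"] not in set(shared):
                continue
            z_gwas = float(zs.loc[lead["SNP"], "Z"])
            n_gwas = float(zs.loc[lead["SNP"], "N"])
            t_smr, p_smr = smr_mod.smr_test(z_gwas, z_pqtl)
            b_xy = (z_gwas / np.sqrt(n_gwas)) / float(lead["BETA"])
            gwas_bse = pd.DataFrame(
                {"SNP": shared,
                 "BETA": zs["Z"].to_numpy() / np.sqrt(zs["N"].to_numpy(dtype=float)),
                 "SE": 1.0 / np.sqrt(zs["N"].to_numpy(dtype=float))}
            )
            instruments = smr_mod.select_heidi_instruments(gps, ld_r, lead["SNP"])
            heidi = smr_mod.heidi_test(
                instruments, gwas_bse, gps[["SNP", "BETA", "SE"]], ld_r, lead["SNP"],
                gene=gene, trait=t, seed=stage_seed(seed, f"heidi:{gene}:{t}") % (2**31),
            )
            labf_gwas = coloc_mod.abf_from_z(zs["Z"].to_numpy(), zs["N"].to_numpy(dtype=float))
            labf_pqtl = coloc_mod.wakefield_abf(gps["BETA"].to_numpy(), gps["SE"].to_numpy())
            crec = coloc_mod.coloc_posteriors(labf_gwas, labf_pqtl, gene=gene, trait=t)
            fdr_p = float(xwas.loc[(xwas["GENE"] == gene) & (xwas["TRAIT"] == t), "FDR"].iloc[0])
            smr_rows.append(
                {"GENE": gene, "TRAIT": t, "SNP": lead["SNP"], "MODE": "cis", "B_XY": b_xy,
                 "T": t_smr, "P_SMR": p_smr, "P_HEIDI": heidi.p_heidi,
                 "N_HEIDI": heidi.n_instruments, "SKIP_REASON": heidi.reason}
            )
            coloc_rows.append(
                {"GENE": gene, "TRAIT": t, "NSNP": crec.n_snps,
                 **{f"PP{i}": crec.pp[i] for i in range(5)}}
            )
            call = calls_mod.call_cis_causal(
                gene, t, fdr_p, p_smr, heidi.p_heidi, crec.pp4, thresholds
            )
            if call is not None:
                cis_calls.append(call)
    smr_table = pd.DataFrame(smr_rows)
    coloc_table = pd.DataFrame(coloc_rows)

    # trans arm
    trans_pqtl = trans_smr_table = None
    trans_calls = []
    if with_trans:
        trans_frames, trans_rows = [], []
        for t in traits:
            clumped = qtl_mod.clump_gwas_hits(bundle.sumstats[t], bundle.panel)
            if clumped.empty:
                continue
            scan = qtl_mod.trans_pqtl_scan(
                clumped, bundle.cohort, bundle.abundance, covariates, bundle.genes
            )
            scan = scan.assign(TRAIT=t)
            trans_frames.append(scan)
            sig_trans = scan.loc[scan["TRANS"] & scan["SIGNIFICANT"]].sort_values("P", kind="mergesort")
            # one record per gene: the strongest trans instrument
            sig_trans = sig_trans.drop_duplicates(subset=["GENE"], keep="first")
            if sig_trans.empty:
                continue
            threshold = smr_mod.bonferroni_trans_threshold(len(sig_trans))
            for _, rec in sig_trans.iterrows():
                snp_row = bundle.panel.snps.set_index("SNP").loc[rec["SNP"]]
                local_snps = bundle.cohort.snps.loc[
                    (bundle.cohort.snps["CHR"].astype(str) == str(snp_row["CHR"]))
                    & (bundle.cohort.snps["BP"] >= int(snp_row["BP"]) - smr_mod.TRANS_WINDOW_BP)
                    & (bundle.cohort.snps["BP"] <= int(snp_row["BP"]) + smr_mod.TRANS_WINDOW_BP)
                ]
                local = _local_pqtl_scan(bundle, covariates, rec["GENE"], local_snps)
                ld_local = _panel_ld(bundle.panel, local["SNP"].tolist())
                try:
                    smr_rec, heidi_rec = smr_mod.trans_smr(
                        rec, bundle.sumstats[t], local, ld_local, bundle.genes, trait=t,
                        seed=stage_seed(seed, f"theidi:{rec['GENE']}:{t}") % (2**31),
                    )
                except (ValueError, KeyError) as exc:
                    log.info("trans_smr: %s/%s skipped (%s)", rec["GENE"], t, exc)
                    continue
                trans_rows.append(
                    {"GENE": smr_rec.gene, "TRAIT": t, "SNP": smr_rec.snp, "MODE": "trans",
                     "B_XY": smr_rec.b_xy, "T": smr_rec.t_smr, "P_SMR": smr_rec.p_smr,
                     "P_HEIDI": heidi_rec.p_heidi, "N_HEIDI": heidi_rec.n_instruments,
                     "PQTL_P": rec["P"], "SMR_THRESHOLD": threshold,
                     "SKIP_REASON": heidi_rec.reason}
                )
                call = calls_mod.call_trans_causal(
                    smr_rec.gene, t, float(rec["P"]), smr_rec.p_smr, heidi_rec.p_heidi,
                    threshold, thresholds,
                )
                if call is not None:
                    trans_calls.append(call)
        trans_pqtl = pd.concat(trans_frames, ignore_index=True) if trans_frames else None
        trans_smr_table = pd.DataFrame(trans_rows) if trans_rows else None

    causal = calls_mod.calls_table(cis_calls + trans_calls)
    if not causal.empty:
        causal = causal.drop_duplicates(subset=["GENE", "TRAIT", "MODE"], keep="first").reset_index(drop=True)
    sharing = (
        calls_mod.tabulate_sharing(causal, bundle.groups) if not causal.empty else None
    )

    extras = {}
    if with_ppi and bundle.ppi is not None and not causal.empty:
        network = ppi_mod.filter_physical(ppi_mod.PpiNetwork.from_edges(bundle.ppi))
        by_group: dict[str, set] = {}
        for row in causal.itertuples(index=False):
            by_group.setdefault(bundle.groups[row.TRAIT], set()).add(row.GENE)
        gnames = sorted(by_group)
        if len(gnames) >= 2:
            a, b = by_group[gnames[0]], by_group[gnames[1]]
            if a and b:
                extras["ppi_bootstrap"] = ppi_mod.ppi_bootstrap_test(
                    network, a, b, n_iterations=ppi_iterations, seed=stage_seed(seed, "ppi") % (2**31)
                )
    return PipelineResult(
        ld_scores=ld_scores, rg_table=rg_table, heritability=heritability, weights=weights,
        xwas=xwas, cis_pqtl=cis_pqtl, smr=smr_table, coloc=coloc_table,
        trans_pqtl=trans_pqtl, trans_smr=trans_smr_table, causal_calls=causal,
        sharing=sharing, extras=extras,
    )


def save_result(res: PipelineResult, out_dir: str | Path, thresholds: PipelineThresholds | None = None) -> None:
    """Write every stage's table to a directory (TSV + JSON summary)."""
    from .io import write_json, write_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(res.ld_scores, out / "ldscores.tsv")
    if res.rg_table is not None:
        write_table(res.rg_table, out / "rg_matrix.tsv")
    write_table(res.heritability, out / "heritability.tsv")
    for trait, sub in res.xwas.groupby("TRAIT"):
        write_table(sub, out / f"xwas_{trait}.tsv")
    if not res.smr.empty:
        for trait, sub in res.smr.groupby("TRAIT"):
            write_table(sub, out / f"smr_{trait}.tsv")
    if not res.coloc.empty:
        for trait, sub in res.coloc.groupby("TRAIT"):
            write_table(sub, out / f"coloc_{trait}.tsv")
    write_table(res.cis_pqtl, out / "cis_pqtl.tsv")
    if res.trans_pqtl is not None:
        write_table(res.trans_pqtl, out / "trans_pqtl.tsv")
    write_table(res.causal_calls, out / "causal_calls.tsv")
    if res.sharing is not None:
        write_table(res.sharing.per_trait, out / "sharing_summary.tsv")
        cross = pd.DataFrame(
            [{"GROUP1": g1, "GROUP2": g2, "GENES": ",".join(genes)}
             for (g1, g2), genes in res.sharing.cross_group.items()]
        )
        write_table(cross, out / "cross_group_shared.tsv")
    summary = {"thresholds": vars(thresholds or PipelineThresholds())}
    if "ppi_bootstrap" in res.extras:
        b = res.extras["ppi_bootstrap"]
        summary["ppi_bootstrap"] = {"s0": b.s0, "p": b.p, "fold": b.fold, "N": b.n_iterations, "seed": b.seed}
    write_json(summary, out / "run_summary.json")


def _local_pqtl_scan(bundle: StudyBundle, covariates: pd.DataFrame, gene: str, local_snps: pd.DataFrame) -> pd.DataFrame:
    """Marginal pQTL scan of one gene against an explicit SNP window (used
    for HEIDI around a trans instrument)."""
    c = qtl_mod.check_covariates(covariates)
    ones_c = np.column_stack([np.ones(bundle.cohort.n_samples), c])
    q, _ = np.linalg.qr(ones_c)
    idx = bundle.cohort.index_of(local_snps["SNP"])
    x = bundle.cohort.standardized()[:, idx]
    xr = x - q @ (q.T @ x)
    y = bundle.abundance[gene].to_numpy(dtype=float)
    yr = y - q @ (q.T @ y)
    df_resid = bundle.cohort.n_samples - ones_c.shape[1] - 1
    beta, se, p = qtl_mod._marginal_ols(xr, yr, df_resid)
    return pd.DataFrame({"SNP": local_snps["SNP"].to_numpy(), "BETA": beta, "SE": se, "P": p})
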
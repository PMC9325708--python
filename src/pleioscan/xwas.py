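"""Proteome/transcriptome-wide association from weights + summary statistics.

The gene-level statistic is z = w'Z / sqrt(w'Rw): trained cis weights w,
harmonized GWAS z-vector Z and reference-panel LD submatrix R over the
weight SNPs.  The same operation serves the protein (PWAS) and mRNA (TWAS)
arms; the molecular modality is a label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypePanel
from .ldsc import harmonize
from .qtl import WeightSet

log = logging.getLogger(__name__)

LD_RIDGE = 1e-6  # diagonal regularization of the LD submatrix


@dataclass
class XwasRecord:
    gene: str
    trait: str
    z: float
    p: float
    model: str
    n_snps: int
    q: float | None = None


def xwas_z(weights: WeightSet, ss: pd.DataFrame, panel: GenotypePanel, trait: str = "trait") -> XwasRecord:
    """Summary-based association z-score for one gene.

    Weight SNPs absent from the harmonized summary statistics are dropped
    (weights used as-is over the intersection, no renormalization).
    """
    # align both the GWAS z and the weights to the panel's allele coding
    ss_h = harmonize(ss, panel.snps[["SNP", "A1", "A2"]])
    w_df = weights.snps.assign(Z=np.asarray(weights.weights, dtype=float), N=1)
    w_h = harmonize(w_df, panel.snps[["SNP", "A1", "A2"]])
    avail = ss_h.set_index("SNP")["Z"]
    mask = w_h["SNP"].isin(avail.index).to_numpy()
    if mask.sum() == 0:
        raise ValueError(f"no weight SNPs present in summary statistics for {weights.gene}")
    if mask.sum() < len(weights.weights):
        log.info("xwas_z: %s dropped %d of %d weight SNPs missing from sumstats",
                 weights.gene, len(weights.weights) - int(mask.sum()), len(weights.weights))
    snp_ids = w_h.loc[mask, "SNP"]
    w = w_h.loc[mask, "Z"].to_numpy(dtype=float)
    z_vec = avail.loc[snp_ids].to_numpy(dtype=float)
    idx = panel.index_of(snp_ids)
    x = panel.standardized()[:, idx]
    r = x.T @ x / panel.n_samples
    r[np.diag_indices_from(r)] += LD_RIDGE
    denom = float(w @ r @ w)
    if denom < 1e-8:
        raise ValueError(f"degenerate weight variance for gene {weights.gene}")
    z = float(w @ z_vec / np.sqrt(denom))
    return XwasRecord(
        gene=weights.gene, trait=trait, z=z, p=float(2.0 * stats.norm.sf(abs(z))),
        model=weights.model, n_snps=int(mask.sum()),
    )


def run_xwas(
    weight_sets: list[WeightSet], ss: pd.DataFrame, panel: GenotypePanel, trait: str = "trait",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One record per gene with Benjamini-Hochberg FDR within the trait."""
    records = []
    for ws in weight_sets:
        try:
            records.append(xwas_z(ws, ss, panel, trait))
        except ValueError as exc:
            log.info("run_xwas: skipping %s (%s)", ws.gene, exc)
    if not records:
        raise ValueError("no gene with usable weights")
    df = pd.DataFrame([vars(r) for r in records]).drop(columns=["q"])
    df["FDR"] = multipletests(df["p"], method="fdr_bh")[1]
    df["SIGNIFICANT"] = df["FDR"] < fdr
    return df.rename(columns={"gene": "GENE", "trait": "TRAIT", "z": "Z", "p": "P",
                              "model": "MODEL", "n_snps": "NSNP"})
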
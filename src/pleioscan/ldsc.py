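"""LD score regression: SNP heritability and pairwise genetic correlation.

The univariate model regresses chi-square statistics on N*l_j/M with a free
intercept (separating polygenicity from confounding); the bivariate model
regresses z1*z2 on sqrt(N1*N2)*l_j/M, whose free intercept absorbs sample
overlap.  Standard errors come from a delete-one block jackknife over
contiguous SNP blocks.  Both regressions share the same first-pass-derived
heteroskedasticity weights so a trait regressed on itself returns rg = 1
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypePanel

log = logging.getLogger(__name__)

CHISQ_FILTER = 80.0  # chi^2 > 80: SNPs with extremely large effects are removed
AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class H2Estimate:
    h2: float
    intercept: float
    se: float
    n_snps: int


@dataclass
class RgEstimate:
    trait1: str
    trait2: str
    rg: float
    se: float
    z: float
    p: float
    h2_1: float
    h2_2: float
    intercept_1: float
    intercept_2: float
    gencov_intercept: float
    n_snps: int
    flagged: bool = False
    q: float | None = None
    note: str = ""


def compute_ld_scores(panel: GenotypePanel, window_kb: float = 1000.0, adjust: bool = True) -> pd.DataFrame:
    """Per-SNP LD scores l_j = sum over window of (adjusted) r^2.

    The unbiased adjustment r2_adj = r2 - (1 - r2)/(n - 2) removes the
    finite-panel upward bias; the self term contributes exactly 1 either way.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    n = panel.n_samples
    if n < 3:
        raise ValueError("panel needs >= 3 samples")
    x = panel.standardized()
    bp = panel.snps["BP"].to_numpy()
    chrom = panel.snps["CHR"].to_numpy()
    window = window_kb * 1000.0
    l2 = np.zeros(panel.n_snps)
    for c in pd.unique(chrom):
        cols = np.flatnonzero(chrom == c)
        xp, bpc = x[:, cols], bp[cols]
        m = len(cols)
        chunk = 512
        for s in range(0, m, chunk):
            e = min(s + chunk, m)
            lo = np.searchsorted(bpc, bpc[s] - window, side="left")
            hi = np.searchsorted(bpc, bpc[e - 1] + window, side="right")
            r = xp[:, lo:hi].T @ xp[:, s:e] / n
            r2 = r * r
            if adjust:
                r2 = r2 - (1.0 - r2) / (n - 2)
            mask = np.abs(bpc[lo:hi, None] - bpc[None, s:e]) <= window
            l2[cols[s:e]] = np.sum(r2 * mask, axis=0)
    if adjust:
        l2 = np.maximum(l2, 0.0)
    return pd.DataFrame({"SNP": panel.snps["SNP"].to_numpy(), "L2": l2})


def harmonize(ss: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Align summary statistics to a reference allele coding.

    Matching A1/A2 pass through; swapped A1/A2 get their z negated;
    strand-ambiguous (A/T, C/G) and unmatched SNPs are dropped.
    """
    ref = reference[["SNP", "A1", "A2"]].rename(columns={"A1": "REF_A1", "A2": "REF_A2"})
    merged = ss.merge(ref, on="SNP", how="inner")
    if merged.empty:
        raise ValueError("no overlapping SNPs between summary statistics and reference")
    ambiguous = [frozenset((a1, a2)) in AMBIGUOUS for a1, a2 in zip(merged["A1"], merged["A2"])]
    merged = merged.loc[~np.asarray(ambiguous)].copy()
    same = (merged["A1"] == merged["REF_A1"]) & (merged["A2"] == merged["REF_A2"])
    swapped = (merged["A1"] == merged["REF_A2"]) & (merged["A2"] == merged["REF_A1"])
    keep = same | swapped
    merged = merged.loc[keep].copy()
    merged.loc[swapped[keep], "Z"] = -merged.loc[swapped[keep], "Z"]
    if "FREQ" in merged.columns:
        merged.loc[swapped[keep], "FREQ"] = 1.0 - merged.loc[swapped[keep], "FREQ"]
    merged["A1"] = merged.pop("REF_A1")
    merged["A2"] = merged.pop("REF_A2")
    log.info(
        "harmonize: %d retained, %d sign-flipped, %d ambiguous dropped, %d mismatched dropped",
        len(merged), int(swapped[keep].sum()), int(np.sum(ambiguous)), int((~keep).sum()),
    )
    if merged.empty:
        raise ValueError("no SNPs left after allele harmonization")
    cols = [c for c in ["SNP", "CHR", "BP", "A1", "A2", "Z", "N", "FREQ"] if c in merged.columns]
    return merged[cols].reset_index(drop=True)


def filter_large_effects(ss: pd.DataFrame, threshold: float = CHISQ_FILTER) -> pd.DataFrame:
    """Drop SNPs with chi^2 = z^2 strictly above the threshold."""
    chisq = ss["Z"].to_numpy() ** 2
    keep = chisq <= threshold
    log.info("filter_large_effects: removed %d of %d SNPs (chi2 > %g)", int((~keep).sum()), len(ss), threshold)
    return ss.loc[keep].reset_index(drop=True)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    a = np.column_stack([np.ones_like(x), x])
    aw = a * w[:, None]
    xtx = a.T @ aw
    xty = aw.T @ y
    coef = np.linalg.solve(xtx, xty)
    return coef  # (intercept, slope)


def _block_edges(n: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, n, min(n_blocks, n) + 1).astype(int)


def _jackknife_ratios(stat_fn, n: int, n_blocks: int):
    """Delete-one-block jackknife of a statistic computed from index masks."""
    edges = _block_edges(n, n_blocks)
    thetas = []
    for b in range(len(edges) - 1):
        mask = np.ones(n, bool)
        mask[edges[b] : edges[b + 1]] = False
        thetas.append(stat_fn(mask))
    thetas = np.asarray(thetas, dtype=float)
    bmm = len(thetas)
    se = np.sqrt((bmm - 1) / bmm * np.sum((thetas - thetas.mean()) ** 2))
    return se


def _merge(ss: pd.DataFrame, ldscores: pd.DataFrame) -> pd.DataFrame:
    df = ss.merge(ldscores, on="SNP", how="inner")
    if "CHR" in df.columns and "BP" in df.columns:
        df = df.sort_values(["CHR", "BP"], kind="mergesort")
    return df.reset_index(drop=True)


def _first_pass_h2(chisq, x):
    coef = _wls(x, chisq, np.ones_like(x))
    return float(np.clip(coef[1], 0.0, 2.0))


def estimate_h2(
    ss: pd.DataFrame, ldscores: pd.DataFrame, M: int | None = None, n_blocks: int = 200
) -> H2Estimate:
    """Univariate LD score regression: chi^2 on N*l/M with free intercept."""
    df = _merge(ss, ldscores)
    if len(df) < 200:
        raise ValueError(f"only {len(df)} SNPs after merging; need >= 200")
    M = M or len(df)
    ell = df["L2"].to_numpy()
    if np.ptp(ell) < 1e-12:
        raise ValueError("degenerate design: constant LD scores")
    n = df["N"].to_numpy(dtype=float)
    chisq = df["Z"].to_numpy() ** 2
    x = n * ell / M
    h0 = _first_pass_h2(chisq, x)
    w = 1.0 / (1.0 + n * h0 * ell / M) ** 2
    coef = _wls(x, chisq, w)

    def slope_of(mask):
        return _wls(x[mask], chisq[mask], w[mask])[1]

    se = _jackknife_ratios(slope_of, len(df), n_blocks)
    return H2Estimate(h2=float(coef[1]), intercept=float(coef[0]), se=float(se), n_snps=len(df))


def estimate_rg(
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    ldscores: pd.DataFrame,
    M: int | None = None,
    n_blocks: int = 200,
    trait1: str = "trait1",
    trait2: str = "trait2",
) -> RgEstimate:
    """Bivariate LD score regression; rg = gencov / sqrt(h2_1 * h2_2)."""
    ss2 = harmonize(ss2, ss1[["SNP", "A1", "A2"]])
    df = ss1.merge(ss2[["SNP", "Z", "N"]], on="SNP", suffixes=("_1", "_2")).merge(ldscores, on="SNP")
    if "CHR" in df.columns and "BP" in df.columns:
        df = df.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    M = M or len(df)
    ell = df["L2"].to_numpy()
    n1 = df["N_1"].to_numpy(dtype=float)
    n2 = df["N_2"].to_numpy(dtype=float)
    z1 = df["Z_1"].to_numpy()
    z2 = df["Z_2"].to_numpy()
    x1, x2 = n1 * ell / M, n2 * ell / M
    xc = np.sqrt(n1 * n2) * ell / M
    h10 = _first_pass_h2(z1**2, x1)
    h20 = _first_pass_h2(z2**2, x2)
    w1 = 1.0 / (1.0 + n1 * h10 * ell / M) ** 2
    w2 = 1.0 / (1.0 + n2 * h20 * ell / M) ** 2
    wc = 1.0 / ((1.0 + n1 * h10 * ell / M) * (1.0 + n2 * h20 * ell / M))

    def rg_of(mask):
        c1 = _wls(x1[mask], z1[mask] ** 2, w1[mask])
        c2 = _wls(x2[mask], z2[mask] ** 2, w2[mask])
        cc = _wls(xc[mask], (z1 * z2)[mask], wc[mask])
        denom = c1[1] * c2[1]
        if denom <= 0:
            return np.nan, c1, c2, cc
        return float(cc[1] / np.sqrt(denom)), c1, c2, cc

    rg, c1, c2, cc = rg_of(np.ones(len(df), bool))
    if not np.isfinite(rg):
        return RgEstimate(
            trait1, trait2, np.nan, np.nan, np.nan, np.nan,
            float(c1[1]), float(c2[1]), float(c1[0]), float(c2[0]), float(cc[0]),
            len(df), flagged=True, note="nonpositive heritability estimate",
        )
    se = _jackknife_ratios(lambda m: rg_of(m)[0], len(df), n_blocks)
    zstat = rg / se if se > 0 else np.inf * np.sign(rg)
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    return RgEstimate(
        trait1=trait1, trait2=trait2, rg=float(rg), se=float(se), z=float(zstat), p=p,
        h2_1=float(c1[1]), h2_2=float(c2[1]), intercept_1=float(c1[0]), intercept_2=float(c2[0]),
        gencov_intercept=float(cc[0]), n_snps=len(df), flagged=bool(abs(rg) > 1.25),
    )


def rg_matrix_fdr(estimates: list[RgEstimate]) -> pd.DataFrame:
    """Benjamini-Hochberg across all trait pairs, with significance tiers."""
    if not estimates:
        raise ValueError("need at least one rg estimate")
    rows = [vars(e).copy() for e in estimates]
    df = pd.DataFrame(rows)
    ok = df["p"].notna().to_numpy()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["q"] = q
    df["tier"] = pd.cut(
        df["q"], bins=[-np.inf, 0.001, 0.01, 0.05, np.inf], labels=["***", "**", "*", ""]
    ).astype(str)
    return df.drop(columns=["note"])
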
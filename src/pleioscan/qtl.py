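"""Molecular-cohort models: cis heritability screen, predictive cis weights,
and cis/trans pQTL mapping.

Heritability uses Haseman-Elston regression on the cis genetic relationship
matrix (closed-form, deterministic), with a one-sided p from a
block-jackknife over samples.  Genes passing the screen (p < 0.01, outside
the HLA region) get cis weights from the best of four models -- top SNP,
ridge (BLUP analog), lasso, elastic net -- chosen by 5-fold cross-validated
R^2.  pQTL scans are ordinary least squares with covariates (including
genotype principal components) residualized out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold

from ._rng import stage_seed
from .io import GenotypePanel

log = logging.getLogger(__name__)

CIS_WINDOW_BP = 500_000
GWAS_SIG = 5e-8
HERITABILITY_P = 0.01
HLA_REGION = ("6", 25_000_000, 34_000_000)  # chr6:25-34 Mb, configurable


@dataclass
class GeneHeritability:
    gene: str
    h2: float  # raw HE estimate (may fall outside [0, 1])
    h2_clamped: float
    se: float
    p: float
    heritable: bool
    hla_excluded: bool
    n_cis_snps: int


@dataclass
class WeightSet:
    gene: str
    snps: pd.DataFrame  # SNP A1 A2 aligned to weights
    weights: np.ndarray
    model: str  # top-SNP | ridge | lasso | elastic-net
    cv_r2: float


@dataclass
class Pi1Estimate:
    pi1: float
    lambda_grid: list
    n_pvalues: int


def cis_window(gene: str, genes: pd.DataFrame, snps: pd.DataFrame, window_bp: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """SNPs on the gene's chromosome with BP in [start - w, end + w], inclusive."""
    row = genes.loc[genes["GENE"] == gene]
    if row.empty:
        raise KeyError(f"unknown gene {gene}")
    row = row.iloc[0]
    mask = (
        (snps["CHR"].astype(str) == str(row["CHR"]))
        & (snps["BP"] >= row["START"] - window_bp)
        & (snps["BP"] <= row["END"] + window_bp)
    )
    return snps.loc[mask]


def in_hla(gene: str, genes: pd.DataFrame, region=HLA_REGION) -> bool:
    row = genes.loc[genes["GENE"] == gene].iloc[0]
    chrom, lo, hi = region
    return str(row["CHR"]) == chrom and row["END"] >= lo and row["START"] <= hi


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    c = np.column_stack([np.ones(len(y)), covariates]) if covariates.size else np.ones((len(y), 1))
    q, _ = np.linalg.qr(c)
    return y - q @ (q.T @ y)


def check_covariates(covariates: pd.DataFrame) -> np.ndarray:
    c = covariates.to_numpy(dtype=float)
    if c.size:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(c)), c]))
        if rank < c.shape[1] + 1:
            corr = np.corrcoef(c, rowvar=False)
            np.fill_diagonal(corr, 0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"rank-deficient covariates: column {covariates.columns[j]!r} is collinear"
            )
    return c


def genotype_pcs(panel: GenotypePanel, n_components: int = 10, seed: int = 0) -> pd.DataFrame:
    """Principal components of the standardized genotype matrix."""
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(panel.standardized())
    return pd.DataFrame(scores, index=panel.samples, columns=[f"PC{i+1}" for i in range(n_components)])


# ---------------------------------------------------------------------------
# heritability


def estimate_cis_h2(
    cohort: GenotypePanel,
    abundance: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    gene: str,
    genes: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
    n_jackknife_blocks: int = 100,
    hla_region=HLA_REGION,
) -> GeneHeritability:
    """Haseman-Elston regression of phenotype cross-products on cis-GRM entries."""
    y = np.asarray(abundance, dtype=float)
    n = len(y)
    if n < 30:
        raise ValueError("need >= 30 cohort samples")
    if np.std(y) == 0:
        raise ValueError(f"constant abundance for gene {gene}")
    cis = cis_window(gene, genes, cohort.snps, window_bp)
    if cis.empty:
        raise ValueError(f"gene {gene} has no cis SNPs")
    idx = cohort.index_of(cis["SNP"])
    x = cohort.standardized()[:, idx]
    m = x.shape[1]
    y = _residualize(y, check_covariates(covariates))
    y = y / y.std()
    k = x @ x.T / m
    u = k @ y
    kd = np.diag(k).copy()
    # off-diagonal sums via full sums minus diagonal
    s1 = 0.5 * (y @ u - np.sum(kd * y * y))
    s2 = 0.5 * (np.sum(k * k) - np.sum(kd * kd))
    h2 = s1 / s2
    # per-sample contributions for the delete-block jackknife
    t1 = y * (u - kd * y)  # sum over j != i of K_ij y_i y_j
    t2 = np.sum(k * k, axis=1) - kd * kd
    edges = np.linspace(0, n, min(n_jackknife_blocks, n) + 1).astype(int)
    thetas = []
    for b in range(len(edges) - 1):
        sl = slice(edges[b], edges[b + 1])
        kb = k[sl, sl]
        yb = y[sl]
        w1 = 0.5 * (yb @ kb @ yb - np.sum(np.diag(kb) * yb * yb))
        w2 = 0.5 * (np.sum(kb * kb) - np.sum(np.diag(kb) ** 2))
        # sum of per-sample contributions over B counts B-B pairs twice
        s1b = s1 - (np.sum(t1[sl]) - w1)
        s2b = s2 - (np.sum(t2[sl]) - w2)
        thetas.append(s1b / s2b if s2b > 0 else np.nan)
    thetas = np.asarray(thetas)
    thetas = thetas[np.isfinite(thetas)]
    bn = len(thetas)
    se = float(np.sqrt((bn - 1) / bn * np.sum((thetas - thetas.mean()) ** 2))) if bn > 1 else np.nan
    p = float(stats.norm.sf(h2 / se)) if se and np.isfinite(se) and se > 0 else np.nan
    hla = in_hla(gene, genes, hla_region)
    return GeneHeritability(
        gene=gene,
        h2=float(h2),
        h2_clamped=float(np.clip(h2, 0.0, 1.0)),
        se=se,
        p=p,
        heritable=bool(p < HERITABILITY_P and not hla),
        hla_excluded=hla,
        n_cis_snps=m,
    )


# ---------------------------------------------------------------------------
# weights


def _cv_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot) if ss_tot > 0 else np.nan


def _fit_model(tag: str, x: np.ndarray, y: np.ndarray, h2_guess: float) -> np.ndarray:
    m = x.shape[1]
    if tag == "top-SNP":
        xx = np.sum(x * x, axis=0)
        xx[xx == 0] = np.inf
        betas = (x.T @ y) / xx
        tstat = np.abs(betas) * np.sqrt(xx)
        j = int(np.argmax(tstat))
        w = np.zeros(m)
        w[j] = betas[j]
        return w
    if tag == "ridge":
        h2 = float(np.clip(h2_guess, 0.01, 0.99))
        model = Ridge(alpha=m * (1.0 - h2) / h2, fit_intercept=True)
    elif tag == "lasso":
        model = LassoCV(cv=3, alphas=20, max_iter=5000, fit_intercept=True)
    else:  # elastic-net
        model = ElasticNetCV(l1_ratio=0.5, cv=3, alphas=20, max_iter=5000, fit_intercept=True)
    model.fit(x, y)
    return np.asarray(model.coef_, dtype=float)


MODEL_TAGS = ("top-SNP", "ridge", "lasso", "elastic-net")


def fit_weights(
    cohort: GenotypePanel,
    abundance: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    gene: str,
    genes: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
    h2_guess: float = 0.3,
    seed: int = 0,
    n_folds: int = 5,
) -> WeightSet | None:
    """Train cis weights; winner by 5-fold CV R^2, refit on the full cohort.

    Returns None (with a logged reason) when no model achieves positive
    cross-validated R^2.
    """
    cis = cis_window(gene, genes, cohort.snps, window_bp)
    idx = cohort.index_of(cis["SNP"])
    x = cohort.standardized()[:, idx]
    y = _residualize(np.asarray(abundance, dtype=float), check_covariates(covariates))
    y = y / y.std()
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=stage_seed(seed, f"weights:{gene}") % (2**32))
    oof = {tag: np.zeros_like(y) for tag in MODEL_TAGS}
    for train, test in kf.split(x):
        for tag in MODEL_TAGS:
            w = _fit_model(tag, x[train], y[train], h2_guess)
            oof[tag][test] = x[test] @ w
    scores = {tag: _cv_r2(y, oof[tag]) for tag in MODEL_TAGS}
    best = max(scores, key=lambda t: scores[t])
    if not np.isfinite(scores[best]) or scores[best] <= 0:
        log.info("fit_weights: gene %s dropped (best CV R^2 = %.3f)", gene, scores[best])
        return None
    w = _fit_model(best, x, y, h2_guess)
    if not np.any(w != 0):
        log.info("fit_weights: gene %s dropped (all-zero refit weights)", gene)
        return None
    keep = w != 0
    return WeightSet(
        gene=gene,
        snps=cis.iloc[np.flatnonzero(keep)][["SNP", "A1", "A2"]].reset_index(drop=True),
        weights=w[keep],
        model=best,
        cv_r2=scores[best],
    )


# ---------------------------------------------------------------------------
# pQTL scans


def _marginal_ols(xr: np.ndarray, yr: np.ndarray, df_resid: int):
    """Vectorized simple OLS of residualized y on each residualized column."""
    xx = np.sum(xr * xr, axis=0)
    xy = xr.T @ yr
    yy = float(yr @ yr)
    xx_safe = np.where(xx > 0, xx, np.inf)
    beta = xy / xx_safe
    rss = np.maximum(yy - beta * xy, 0.0)
    se = np.sqrt(rss / (df_resid * xx_safe))
    with np.errstate(divide="ignore", invalid="ignore"):
        # a perfect fit (zero residual) is an infinitely strong association
        tstat = np.where(se > 0, beta / se, np.where(beta != 0, np.inf, 0.0))
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    return beta, se, p


def cis_pqtl_scan(
    cohort: GenotypePanel,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
) -> pd.DataFrame:
    """Per-gene marginal OLS of abundance on every cis SNP.

    Returns one row per gene x cis SNP with beta, se, p, distance and a LEAD
    flag (minimum p per gene; ties broken by smaller position).
    """
    c = check_covariates(covariates)
    x = cohort.standardized()
    ones_c = np.column_stack([np.ones(cohort.n_samples), c])
    q, _ = np.linalg.qr(ones_c)
    xr = x - q @ (q.T @ x)
    df_resid = cohort.n_samples - ones_c.shape[1] - 1
    out = []
    for g in genes.itertuples(index=False):
        cis = cis_window(g.GENE, genes, cohort.snps, window_bp)
        if cis.empty:
            continue
        idx = cohort.index_of(cis["SNP"])
        y = abundance[g.GENE].to_numpy(dtype=float)
        yr = y - q @ (q.T @ y)
        beta, se, p = _marginal_ols(xr[:, idx], yr, df_resid)
        dist = np.maximum.reduce([g.START - cis["BP"].to_numpy(), cis["BP"].to_numpy() - g.END, np.zeros(len(cis), dtype=int)])
        df = pd.DataFrame(
            {"SNP": cis["SNP"].to_numpy(), "GENE": g.GENE, "BETA": beta, "SE": se, "P": p,
             "DISTANCE": dist, "BP": cis["BP"].to_numpy(), "TRANS": False}
        )
        lead = df.sort_values(["P", "BP"], kind="mergesort").index[0]
        df["LEAD"] = False
        df.loc[lead, "LEAD"] = True
        out.append(df)
    return pd.concat(out, ignore_index=True)


def clump_gwas_hits(
    ss: pd.DataFrame,
    panel: GenotypePanel,
    p_threshold: float = GWAS_SIG,
    r2_threshold: float = 0.5,
    window_bp: int = 250_000,
) -> pd.DataFrame:
    """Greedy LD clumping of GWAS-significant SNPs.

    Sort by p ascending; keep a SNP unless it has r^2 >= threshold with an
    already-kept SNP within the window.
    """
    ss = ss.copy()
    ss["P"] = 2.0 * stats.norm.sf(np.abs(ss["Z"]))
    hits = ss.loc[ss["P"] < p_threshold].sort_values(["P", "BP"], kind="mergesort")
    if hits.empty:
        return hits
    x = panel.standardized()
    pos = pd.Index(panel.snps["SNP"])
    kept: list[int] = []
    kept_rows = []
    for row in hits.itertuples(index=False):
        j = pos.get_loc(row.SNP)
        ok = True
        for k, krow in zip(kept, kept_rows):
            if krow.CHR == row.CHR and abs(krow.BP - row.BP) <= window_bp:
                r = float(np.corrcoef(x[:, j], x[:, k])[0, 1])
                if r * r >= r2_threshold:
                    ok = False
                    break
        if ok:
            kept.append(j)
            kept_rows.append(row)
    return pd.DataFrame(kept_rows)


def trans_pqtl_scan(
    clumped: pd.DataFrame,
    cohort: GenotypePanel,
    abundance: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = CIS_WINDOW_BP,
    sig_threshold: float = GWAS_SIG,
) -> pd.DataFrame:
    """Test every clumped GWAS SNP against every gene's abundance.

    A record is flagged TRANS when the SNP lies more than 500 kb from the
    gene (or on another chromosome); SIGNIFICANT marks p < 5e-8.
    """
    if clumped.empty:
        raise ValueError("clumped SNP list is empty")
    c = check_covariates(covariates)
    ones_c = np.column_stack([np.ones(cohort.n_samples), c])
    q, _ = np.linalg.qr(ones_c)
    idx = cohort.index_of(clumped["SNP"])
    x = cohort.standardized()[:, idx]
    xr = x - q @ (q.T @ x)
    y = abundance.to_numpy(dtype=float)
    yr = y - q @ (q.T @ y)
    df_resid = cohort.n_samples - ones_c.shape[1] - 1
    xx = np.sum(xr * xr, axis=0)
    xx_safe = np.where(xx > 0, xx, np.inf)
    num = xr.T @ yr  # SNPs x genes
    yy = np.sum(yr * yr, axis=0)
    beta = num / xx_safe[:, None]
    rss = np.maximum(yy[None, :] - beta * num, 0.0)
    se = np.sqrt(rss / (df_resid * xx_safe[:, None]))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    snp_meta = cohort.snps.set_index("SNP").loc[clumped["SNP"]]
    records = []
    for si, snp in enumerate(clumped["SNP"]):
        bp, chrom = int(snp_meta["BP"].iloc[si]), str(snp_meta["CHR"].iloc[si])
        for gi, g in enumerate(genes.itertuples(index=False)):
            same = str(g.CHR) == chrom
            dist = max(g.START - bp, bp - g.END, 0) if same else -1
            records.append(
                (snp, g.GENE, beta[si, gi], se[si, gi], p[si, gi], dist,
                 (not same) or dist > window_bp, p[si, gi] < sig_threshold)
            )
    out = pd.DataFrame(records, columns=["SNP", "GENE", "BETA", "SE", "P", "DISTANCE", "TRANS", "SIGNIFICANT"])
    return out


def estimate_pi1(pvalues, lam: float = 0.5) -> Pi1Estimate:
    """Storey's pi1 = 1 - pi0 with pi0 = #{p > lambda} / ((1 - lambda) m)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) < 20:
        raise ValueError("need >= 20 p-values")
    pi0 = np.sum(p > lam) / ((1.0 - lam) * len(p))
    return Pi1Estimate(pi1=float(np.clip(1.0 - pi0, 0.0, 1.0)), lambda_grid=[lam], n_pvalues=len(p))
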
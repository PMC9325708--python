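"""Summary-data Mendelian randomization and the HEIDI linkage filter.

SMR tests whether molecular abundance mediates a SNP-trait association via
the ratio estimate b_xy = beta_GWAS / beta_pQTL at the top cis instrument:
T_SMR = z_g^2 z_p^2 / (z_g^2 + z_p^2), chi-square(1).  HEIDI asks whether
b_xy is homogeneous across LD-linked instruments: under a single shared
causal variant (causality/pleiotropy) the deviations d_i = b_xy(i) -
b_xy(top) are zero in expectation, while linkage (two distinct causal
variants) makes them drift.  The HEIDI statistic is the sum of squared
standardized deviations, whose null is a positively weighted sum of
chi-square(1) variables with weights the eigenvalues of the deviation
correlation matrix (Ruben series when well-conditioned; Imhof integral,
saddlepoint, then seeded Monte Carlo as fallbacks).

Instrument selection follows the SMR tool's published defaults: pQTL
p < 1.57e-3, r^2 to the top SNP in [0.05, 0.9], at most the 20 smallest-p
SNPs, at least 3 to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._rng import stage_rng

HEIDI_P_INSTRUMENT = 1.57e-3
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_INSTRUMENTS = 20
HEIDI_MIN_INSTRUMENTS = 3
TRANS_MIN_DISTANCE_BP = 5_000_000
TRANS_WINDOW_BP = 500_000


@dataclass
class SmrRecord:
    gene: str
    trait: str
    snp: str
    b_xy: float
    t_smr: float
    p_smr: float
    mode: str = "cis"  # cis | trans


@dataclass
class HeidiRecord:
    gene: str
    trait: str
    p_heidi: float | None
    n_instruments: int
    skipped: bool = False
    reason: str = ""
    method: str = ""  # ruben | imhof | saddlepoint | monte-carlo


def smr_test(z_gwas: float, z_pqtl: float) -> tuple[float, float]:
    """T_SMR = z_g^2 z_p^2 / (z_g^2 + z_p^2); p from chi-square(1) upper tail."""
    if not (np.isfinite(z_gwas) and np.isfinite(z_pqtl)):
        raise ValueError("z-scores must be finite")
    if z_pqtl == 0:
        raise ValueError("undefined instrument: z_pqtl = 0")
    zg2, zp2 = z_gwas**2, z_pqtl**2
    if zg2 == 0:
        return 0.0, 1.0
    t = zg2 * zp2 / (zg2 + zp2)
    return float(t), float(stats.chi2.sf(t, df=1))


def _ruben_sf(q: float, lam: np.ndarray, max_terms: int = 10_000, tol: float = 1e-14) -> float | None:
    """Ruben's series: Q = sum lam_i chi2_1 expressed as a nonnegative mixture
    of central chi-squares, P(Q > q) = sum_j a_j * SF_chi2(q/beta, k+2j) with
    beta = min(lam).  Exact (to truncation) and accurate arbitrarily far into
    the tail because every term is positive."""
    k = lam.size
    beta = lam.min()
    ratio = 1.0 - beta / lam
    a = np.empty(max_terms)
    a[0] = np.exp(0.5 * np.sum(np.log(beta / lam)))
    g_cache = np.empty(max_terms)
    sf = a[0] * stats.chi2.sf(q / beta, k)
    mass = a[0]
    for j in range(1, max_terms):
        g_cache[j - 1] = np.sum(ratio**j)
        a[j] = np.sum(g_cache[:j][::-1] * a[:j]) / (2.0 * j)
        sf += a[j] * stats.chi2.sf(q / beta, k + 2 * j)
        mass += a[j]
        if 1.0 - mass < tol:
            return float(min(sf + (1.0 - mass), 1.0))  # remaining mass bounds the error
    return None  # slow convergence: ill-conditioned weights


def _saddlepoint_sf(q: float, lam: np.ndarray) -> float | None:
    """Lugannani-Rice saddlepoint tail for a positively weighted chi-square
    sum; accurate on the log scale far into the tail."""
    from scipy.optimize import brentq

    mean = lam.sum()
    if abs(q - mean) < 1e-8 * max(mean, 1.0):
        return None

    def kprime(s):
        return np.sum(lam / (1.0 - 2.0 * s * lam))

    upper = 1.0 / (2.0 * lam.max())
    try:
        s_hat = brentq(lambda s: kprime(s) - q, -1e4, upper * (1 - 1e-12), xtol=1e-14)
    except ValueError:
        return None
    if abs(s_hat) < 1e-10:
        return None
    k = -0.5 * np.sum(np.log1p(-2.0 * s_hat * lam))
    kpp = 2.0 * np.sum(lam**2 / (1.0 - 2.0 * s_hat * lam) ** 2)
    w = np.sign(s_hat) * np.sqrt(2.0 * (s_hat * q - k))
    v = s_hat * np.sqrt(kpp)
    return float(stats.norm.sf(w + np.log(v / w) / w))


def weighted_chi2_sf(q: float, lam: np.ndarray, seed: int = 0, n_mc: int = 100_000) -> tuple[float, str]:
    """Upper tail of sum_i lam_i * chi2_1 at q.

    Ruben's exact mixture series when the eigenvalues are well-conditioned;
    otherwise Imhof's integral, then a Lugannani-Rice saddlepoint, then a
    fixed-seed Monte Carlo estimate as the last resort.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 1e-10]
    if lam.size == 0:
        return 1.0, "degenerate"
    if q <= 0:
        return 1.0, "exact"
    if lam.max() / lam.min() < 1e4:  # well-conditioned: exact series
        p = _ruben_sf(q, lam)
        if p is not None:
            return p, "ruben"

    def integrand(u):
        theta = 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * q * u
        rho = float(np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))
        return np.sin(theta) / (u * rho)

    try:
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                val, err = integrate.quad(integrand, 0, np.inf, limit=2000, epsabs=1e-12, epsrel=1e-10)
        p = 0.5 + val / np.pi
        if np.isfinite(p) and 0 < p <= 1.0 + 1e-9 and err < 0.01 * p:
            return float(min(p, 1.0)), "imhof"
    except Exception:
        pass
    p_sp = _saddlepoint_sf(q, lam)
    if p_sp is not None and np.isfinite(p_sp):
        return float(np.clip(p_sp, 0.0, 1.0)), "saddlepoint"
    rng = stage_rng(seed, "wchi2-mc")
    draws = rng.standard_normal((n_mc, lam.size)) ** 2 @ lam
    p = (1 + np.sum(draws >= q)) / (n_mc + 1)
    return float(p), "monte-carlo"


def select_heidi_instruments(
    pqtl: pd.DataFrame,
    ld_r: pd.DataFrame,
    top_snp: str,
    p_threshold: float = HEIDI_P_INSTRUMENT,
    r2_range: tuple[float, float] = (HEIDI_R2_MIN, HEIDI_R2_MAX),
    max_instruments: int = HEIDI_MAX_INSTRUMENTS,
) -> list[str]:
    """Eligible instruments: pQTL p below threshold, r^2 to the top SNP in
    [r2_min, r2_max], capped at the smallest-p ``max_instruments`` SNPs.
    Returns a list possibly shorter than 3; the caller decides to skip."""
    if top_snp not in set(pqtl["SNP"]):
        raise KeyError(f"top SNP {top_snp} missing from pQTL records")
    df = pqtl.loc[pqtl["SNP"] != top_snp, ["SNP", "P"]].copy()
    r_top = ld_r.loc[df["SNP"], top_snp].to_numpy(dtype=float)
    r2 = r_top**2
    keep = (df["P"].to_numpy() < p_threshold) & (r2 >= r2_range[0]) & (r2 <= r2_range[1])
    df = df.loc[keep].sort_values("P", kind="mergesort")
    return df["SNP"].head(max_instruments).tolist()


def heidi_test(
    instruments: list[str],
    gwas: pd.DataFrame,
    pqtl: pd.DataFrame,
    ld_r: pd.DataFrame,
    top_snp: str,
    gene: str = "gene",
    trait: str = "trait",
    seed: int = 0,
) -> HeidiRecord:
    """Heterogeneity of b_xy across instruments relative to the top SNP.

    ``gwas`` and ``pqtl`` need columns SNP, BETA, SE on a shared scale;
    ``ld_r`` is the signed LD correlation over instruments + top SNP.
    """
    if len(instruments) < HEIDI_MIN_INSTRUMENTS:
        return HeidiRecord(gene, trait, None, len(instruments), skipped=True,
                           reason=f"only {len(instruments)} eligible instruments")
    order = [top_snp] + list(instruments)
    g = gwas.set_index("SNP").loc[order]
    e = pqtl.set_index("SNP").loc[order]
    bg, sg = g["BETA"].to_numpy(float), g["SE"].to_numpy(float)
    be, se_e = e["BETA"].to_numpy(float), e["SE"].to_numpy(float)
    r = ld_r.loc[order, order].to_numpy(dtype=float)
    if np.any(be == 0):
        return HeidiRecord(gene, trait, None, len(instruments), skipped=True, reason="zero pQTL effect")
    bxy = bg / be
    d = bxy[1:] - bxy[0]
    k = len(d)
    # delta-method covariance of d_i; GWAS and pQTL cohorts independent
    cov = np.empty((k, k))
    for a in range(k):
        i = a + 1
        for b in range(a, k):
            j = b + 1
            c = (
                r[i, j] * sg[i] * sg[j] / (be[i] * be[j])
                + bg[i] * bg[j] * r[i, j] * se_e[i] * se_e[j] / (be[i] ** 2 * be[j] ** 2)
                + sg[0] ** 2 / be[0] ** 2
                + bg[0] ** 2 * se_e[0] ** 2 / be[0] ** 4
                - r[i, 0] * sg[i] * sg[0] / (be[i] * be[0])
                - r[j, 0] * sg[j] * sg[0] / (be[j] * be[0])
                - bg[i] * bg[0] * r[i, 0] * se_e[i] * se_e[0] / (be[i] ** 2 * be[0] ** 2)
                - bg[j] * bg[0] * r[j, 0] * se_e[j] * se_e[0] / (be[j] ** 2 * be[0] ** 2)
            )
            cov[a, b] = cov[b, a] = c
    sd = np.sqrt(np.diag(cov))
    if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
        return HeidiRecord(gene, trait, None, k, skipped=True, reason="nonpositive deviation variance")
    zd = d / sd
    corr = cov / np.outer(sd, sd)
    corr = 0.5 * (corr + corr.T)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6:
        raise ValueError("deviation covariance not positive semidefinite")
    stat = float(np.sum(zd**2))
    p, method = weighted_chi2_sf(stat, np.clip(lam, 0.0, None), seed=seed)
    return HeidiRecord(gene, trait, float(p), k, method=method)


def trans_eligible(snp_bp: int, snp_chr: str, gene_start: int, gene_end: int, gene_chr: str) -> bool:
    """SNP and gene must sit at least 5 Mb apart or on different chromosomes."""
    if str(snp_chr) != str(gene_chr):
        return True
    dist = max(gene_start - snp_bp, snp_bp - gene_end, 0)
    return dist >= TRANS_MIN_DISTANCE_BP


def trans_smr(
    trans_record: pd.Series,
    ss: pd.DataFrame,
    local_pqtls: pd.DataFrame,
    ld_r: pd.DataFrame,
    genes: pd.DataFrame,
    trait: str = "trait",
    seed: int = 0,
) -> tuple[SmrRecord, HeidiRecord]:
    """SMR + HEIDI on a trans instrument.

    ``trans_record`` is one row of the trans-pQTL scan (SNP, GENE, BETA, SE,
    P).  ``local_pqtls`` holds the pQTL scan of the 500 kb window centered
    on the instrument (columns SNP, BETA, SE, P); HEIDI instruments are
    drawn from it.
    """
    snp, gene = trans_record["SNP"], trans_record["GENE"]
    grow = genes.loc[genes["GENE"] == gene].iloc[0]
    ssnp = ss.loc[ss["SNP"] == snp]
    if ssnp.empty:
        raise KeyError(f"trans SNP {snp} missing from summary statistics")
    ssnp = ssnp.iloc[0]
    if not trans_eligible(int(ssnp["BP"]), str(ssnp["CHR"]), int(grow["START"]), int(grow["END"]), str(grow["CHR"])):
        raise ValueError(f"pair {snp}/{gene} closer than 5 Mb: ineligible for trans SMR")
    n = float(ssnp["N"])
    se_g = 1.0 / np.sqrt(n)
    z_g = float(ssnp["Z"])
    z_p = float(trans_record["BETA"] / trans_record["SE"])
    t, p = smr_test(z_g, z_p)
    b_xy = (z_g * se_g) / float(trans_record["BETA"])
    smr_rec = SmrRecord(gene=gene, trait=trait, snp=snp, b_xy=float(b_xy), t_smr=t, p_smr=p, mode="trans")
    # restrict the GWAS to the +/-500 kb window around the instrument
    win = ss.loc[(ss["CHR"].astype(str) == str(ssnp["CHR"]))
                 & (ss["BP"] >= int(ssnp["BP"]) - TRANS_WINDOW_BP)
                 & (ss["BP"] <= int(ssnp["BP"]) + TRANS_WINDOW_BP)].copy()
    win["BETA"] = win["Z"] / np.sqrt(win["N"].astype(float))
    win["SE"] = 1.0 / np.sqrt(win["N"].astype(float))
    shared = sorted(set(win["SNP"]) & set(local_pqtls["SNP"]) & set(ld_r.index))
    gwas_loc = win.loc[win["SNP"].isin(shared), ["SNP", "BETA", "SE"]]
    pq_loc = local_pqtls.loc[local_pqtls["SNP"].isin(shared)]
    if snp not in set(pq_loc["SNP"]):
        heidi = HeidiRecord(gene, trait, None, 0, skipped=True, reason="instrument outside local scan")
        return smr_rec, heidi
    instruments = select_heidi_instruments(pq_loc, ld_r, snp)
    heidi = heidi_test(instruments, gwas_loc, pq_loc, ld_r, snp, gene=gene, trait=trait, seed=seed)
    return smr_rec, heidi


def bonferroni_trans_threshold(n_significant_trans_pqtls: int, alpha: float = 0.05) -> float:
    """The multiplicity rule for declaring a trans SMR result significant."""
    if n_significant_trans_pqtls <= 0:
        raise ValueError("no significant trans-pQTLs")
    return alpha / n_significant_trans_pqtls
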
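"""Bayesian colocalization of a GWAS and a molecular-QTL signal per region.

Per-SNP approximate Bayes factors (Wakefield) for each trait are combined by
enumerating the five single-causal-variant hypotheses: H0 no association,
H1/H2 one trait only, H3 two distinct causal variants, H4 one shared causal
variant.  All sums are evaluated in log space; posteriors PP0..PP4 are
normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

DEFAULT_W = 0.15**2  # prior effect variance on the standardized scale
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


@dataclass
class ColocRecord:
    gene: str
    trait: str
    pp: np.ndarray  # PP0..PP4
    n_snps: int
    priors: tuple[float, float, float]

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_abf(beta, se, W: float = DEFAULT_W) -> np.ndarray:
    """Log approximate Bayes factor: with r = W/(W+se^2) and z = beta/se,
    log ABF = 0.5*log(1-r) + z^2 * r / 2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    r = W / (W + se**2)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


def abf_from_z(z, n, W: float = DEFAULT_W) -> np.ndarray:
    """Reconstruct beta/se on the standardized scale (se = 1/sqrt(N)) and
    return the log ABF."""
    se = 1.0 / np.sqrt(np.asarray(n, dtype=float))
    return wakefield_abf(np.asarray(z, dtype=float) * se, se, W)


def coloc_posteriors(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    gene: str = "gene",
    trait: str = "trait",
) -> ColocRecord:
    """Posterior probabilities PP0..PP4 from two aligned log-ABF vectors."""
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.size == 0:
        raise ValueError("need >= 1 shared SNP with ABFs for both traits")
    ls1 = logsumexp(labf1)
    ls2 = logsumexp(labf2)
    ls12 = logsumexp(labf1 + labf2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + ls1
    lh[2] = np.log(p2) + ls2
    # H3 = p1*p2*(S1*S2 - S12); S12 <= S1*S2 always for nonnegative terms
    diff = ls12 - ls1 - ls2
    if diff >= 0:  # single-SNP region or numerical saturation
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + ls1 + ls2 + np.log1p(-np.exp(diff))
    lh[4] = np.log(p12) + ls12
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    return ColocRecord(gene=gene, trait=trait, pp=pp, n_snps=labf1.size, priors=(p1, p2, p12))
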
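"""Decision rules for causal calls, sharing tabulation across trait groups,
and the genetic-correlation-versus-sharing association.

A cis-regulated gene is called "consistent with causality or pleiotropy"
when it passes the XWAS FDR gate and either (SMR p < 0.05 with HEIDI
p > 0.05) or (COLOC PP4 > 0.5).  A trans-regulated gene is called when its
trans-pQTL reaches genome-wide significance, the trans SMR passes the
configured multiplicity rule, and HEIDI does not flag linkage.  All rules
are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PipelineThresholds:
    xwas_fdr: float = 0.05
    smr_p: float = 0.05
    heidi_p: float = 0.05
    pp4: float = 0.5
    gwas_sig: float = 5e-8
    heritability_p: float = 0.01
    trans_multiplicity: str = "bonferroni"  # bonferroni | fdr

    def __post_init__(self) -> None:
        for name in ("xwas_fdr", "smr_p", "heidi_p", "pp4", "gwas_sig", "heritability_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"threshold {name} must lie in (0, 1)")
        if self.trans_multiplicity not in ("bonferroni", "fdr"):
            raise ValueError("trans multiplicity rule must be 'bonferroni' or 'fdr'")


@dataclass
class CausalCall:
    gene: str
    trait: str
    mode: str  # cis | trans
    route: str  # SMR_HEIDI | COLOC | BOTH | TRANS
    stats: dict = field(default_factory=dict)


def call_cis_causal(
    gene: str,
    trait: str,
    xwas_fdr_p: float,
    smr_p: float | None,
    heidi_p: float | None,
    pp4: float | None,
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> CausalCall | None:
    """Criteria A-C (XWAS FDR, SMR, HEIDI) or D-E (XWAS FDR, PP4); the FDR
    gate is shared.  HEIDI-skipped genes (heidi_p None) can only qualify via
    the colocalization route."""
    if smr_p is None and pp4 is None:
        raise ValueError(f"{gene}/{trait}: no SMR and no COLOC record to evaluate")
    if not xwas_fdr_p < thresholds.xwas_fdr:
        return None
    smr_route = (
        smr_p is not None and heidi_p is not None
        and smr_p < thresholds.smr_p and heidi_p > thresholds.heidi_p
    )
    coloc_route = pp4 is not None and pp4 > thresholds.pp4
    if not (smr_route or coloc_route):
        return None
    route = "BOTH" if (smr_route and coloc_route) else ("SMR_HEIDI" if smr_route else "COLOC")
    return CausalCall(
        gene=gene, trait=trait, mode="cis", route=route,
        stats={"FDR_P": xwas_fdr_p, "SMR_P": smr_p, "HEIDI_P": heidi_p, "PP4": pp4},
    )


def call_trans_causal(
    gene: str,
    trait: str,
    pqtl_p: float,
    smr_p: float | None,
    heidi_p: float | None,
    smr_threshold: float,
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> CausalCall | None:
    """Criteria i-iii: trans-pQTL p < 5e-8, trans SMR below the multiplicity
    threshold (Bonferroni 0.05/#significant trans-pQTLs by default), HEIDI
    p > 0.05."""
    if smr_p is None:
        raise ValueError(f"{gene}/{trait}: missing trans SMR record")
    if not (pqtl_p < thresholds.gwas_sig):
        return None
    if not (smr_p < smr_threshold):
        return None
    if heidi_p is None or not (heidi_p > thresholds.heidi_p):
        return None
    return CausalCall(
        gene=gene, trait=trait, mode="trans", route="TRANS",
        stats={"PQTL_P": pqtl_p, "SMR_P": smr_p, "HEIDI_P": heidi_p, "SMR_THRESHOLD": smr_threshold},
    )


def calls_table(calls: list[CausalCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({"GENE": c.gene, "TRAIT": c.trait, "MODE": c.mode, "ROUTE": c.route, **c.stats})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sharing


@dataclass
class SharingSummary:
    per_trait: pd.DataFrame  # TRAIT GROUP CIS TRANS TOTAL + SHARED_<group> columns
    cross_group: dict[tuple[str, str], list[str]]  # unordered group pair -> shared genes


def _causal_sets(calls: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for trait, sub in calls.groupby("TRAIT"):
        out[trait] = set(sub["GENE"])
    return out


def tabulate_sharing(calls: pd.DataFrame, groups: dict[str, str]) -> SharingSummary:
    """Per-trait counts and sharing percentages, mirroring the summary-table
    layout: shared%(t, G) = 100 * |{g causal for t and for >= 1 other trait
    in G}| / |{g causal for t}|; traits with zero calls get undefined (NaN)
    percentages."""
    if calls.empty:
        raise ValueError("no causal calls to tabulate")
    calls = calls.drop_duplicates(subset=["GENE", "TRAIT", "MODE"])
    csets = _causal_sets(calls)
    group_names = sorted(set(groups.values()))
    rows = []
    for trait, group in groups.items():
        sub = calls.loc[calls["TRAIT"] == trait]
        mine = csets.get(trait, set())
        row = {
            "TRAIT": trait,
            "GROUP": group,
            "CIS": int((sub["MODE"] == "cis").sum()),
            "TRANS": int((sub["MODE"] == "trans").sum()),
            "TOTAL": len(mine),
        }
        for g in group_names:
            if not mine:
                row[f"SHARED_{g}"] = np.nan
                continue
            others = set().union(*[csets.get(t, set()) for t in groups if groups[t] == g and t != trait]) \
                if any(groups[t] == g and t != trait for t in groups) else set()
            row[f"SHARED_{g}"] = 100.0 * len(mine & others) / len(mine)
        rows.append(row)
    per_trait = pd.DataFrame(rows)
    cross: dict[tuple[str, str], list[str]] = {}
    for i, g1 in enumerate(group_names):
        for g2 in group_names[i + 1 :]:
            s1 = set().union(*[csets.get(t, set()) for t in groups if groups[t] == g1], set())
            s2 = set().union(*[csets.get(t, set()) for t in groups if groups[t] == g2], set())
            cross[(g1, g2)] = sorted(s1 & s2)
    return SharingSummary(per_trait=per_trait, cross_group=cross)


def format_table(summary: SharingSummary) -> pd.DataFrame:
    """Render the per-trait table with dashes for undefined percentages."""
    df = summary.per_trait.copy()
    for c in df.columns:
        if c.startswith("SHARED_"):
            df[c] = df[c].map(lambda v: "-" if pd.isna(v) else f"{v:.0f}%")
    return df


# ---------------------------------------------------------------------------
# rg vs sharing


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    rx = stats.rankdata(x)
    count, total = 0, 0
    for perm in permutations(range(len(y))):
        ry = stats.rankdata(y[list(perm)])
        r = np.corrcoef(rx, ry)[0, 1]
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def correlate_rg_sharing(
    rg_table: pd.DataFrame,
    calls: pd.DataFrame,
    groups: dict[str, str],
    group_pair: tuple[str, str],
    denominator: str = "second",
) -> tuple[float, float, int]:
    """Spearman correlation between rg and the pairwise sharing percentage
    over cross-group trait pairs.

    Sharing% for the pair (t1 in G1, t2 in G2) defaults to
    100 * |C(t1) n C(t2)| / |C(t2)| (denominator the second group's trait;
    switchable to 'first' or 'union').  Exact permutation p for n < 10,
    normal approximation otherwise.
    """
    g1, g2 = group_pair
    csets = _causal_sets(calls)
    rg_lookup = {}
    for r in rg_table.itertuples(index=False):
        rg_lookup[(r.trait1, r.trait2)] = r.rg
        rg_lookup[(r.trait2, r.trait1)] = r.rg
    xs, ys = [], []
    for t1 in [t for t in groups if groups[t] == g1]:
        for t2 in [t for t in groups if groups[t] == g2]:
            if (t1, t2) not in rg_lookup:
                continue
            c1, c2 = csets.get(t1, set()), csets.get(t2, set())
            denom = {"second": c2, "first": c1, "union": c1 | c2}[denominator]
            if not denom:
                continue
            xs.append(rg_lookup[(t1, t2)])
            ys.append(100.0 * len(c1 & c2) / len(denom))
    if len(xs) < 4:
        raise ValueError(f"only {len(xs)} usable trait pairs; need >= 4")
    x, y = np.asarray(xs), np.asarray(ys)
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) < 10:
        p = _exact_spearman_p(x, y, rho)
    else:
        se = 1.0 / np.sqrt(len(x) - 3)
        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        p = float(2.0 * stats.norm.sf(abs(z) / se))
    return rho, p, len(x)
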
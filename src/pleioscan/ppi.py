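"""Constrained bootstrap test for excess protein-protein interactions
between two gene sets, plus fold/hypergeometric annotation enrichment.

The observed count s0 is the number of physical PPIs with one endpoint in
each set.  The null redraws both sets from the network's node universe,
preserving the set sizes and the number of shared members, and the
one-sided empirical p-value is (1 + sum_i I(s_i >= s0)) / (N + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng

log = logging.getLogger(__name__)

PHYSICAL_TYPES = {"physical association", "association", "colocalization", "direct interaction"}
NONPHYSICAL_TYPES = {"genetic interaction", "synthetic genetic interaction", "suppressive genetic interaction"}


@dataclass
class PpiNetwork:
    nodes: list[str]
    u: np.ndarray  # edge endpoint indices into nodes
    v: np.ndarray
    evidence: np.ndarray  # evidence label per edge

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "PpiNetwork":
        """Build from a SYMBOL_A/SYMBOL_B/EVIDENCE_TYPE table, dropping
        self-loops and duplicate unordered pairs (first label wins)."""
        a = edges["SYMBOL_A"].astype(str).to_numpy()
        b = edges["SYMBOL_B"].astype(str).to_numpy()
        ev = edges["EVIDENCE_TYPE"].astype(str).to_numpy()
        keep = a != b
        a, b, ev = a[keep], b[keep], ev[keep]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        key = pd.Index(lo + "\t" + hi)
        first = ~key.duplicated()
        lo, hi, ev = lo[first], hi[first], ev[first]
        nodes = sorted(set(lo) | set(hi))
        index = {s: i for i, s in enumerate(nodes)}
        u = np.fromiter((index[s] for s in lo), dtype=np.int64, count=len(lo))
        v = np.fromiter((index[s] for s in hi), dtype=np.int64, count=len(hi))
        return cls(nodes=nodes, u=u, v=v, evidence=ev)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.u)


@dataclass
class BootstrapResult:
    s0: int
    null_counts: np.ndarray
    n_iterations: int
    p: float
    fold: float
    seed: int
    fold_infinite: bool = False


@dataclass
class SetEnrichmentResult:
    k: int
    n: int
    K: int
    N_bg: int
    fold: float
    hypergeom_p: float
    fisher_p: float


def filter_physical(network: PpiNetwork) -> PpiNetwork:
    """Keep only edges whose evidence is one of the four physical categories
    (physical association, association, colocalization, direct interaction)."""
    known = np.isin(network.evidence, list(PHYSICAL_TYPES | NONPHYSICAL_TYPES))
    if not known.all():
        for lab in np.unique(network.evidence[~known]):
            log.warning("filter_physical: unknown evidence label %r dropped", lab)
    keep = np.isin(network.evidence, list(PHYSICAL_TYPES))
    log.info("filter_physical: kept %d of %d edges", int(keep.sum()), network.n_edges)
    kept_u, kept_v, kept_ev = network.u[keep], network.v[keep], network.evidence[keep]
    used = sorted(set(network.nodes))  # universe: all symbols seen in the input network
    return PpiNetwork(nodes=used, u=kept_u, v=kept_v, evidence=kept_ev)


def count_between(network: PpiNetwork, set_a, set_b) -> tuple[int, pd.DataFrame]:
    """Number of edges with one endpoint in set A and the other in set B.

    Members shared by both sets count on either side; each unordered edge
    counts once; edges internal to one set's exclusive members do not count.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a or not set_b:
        raise ValueError("both sets must be nonempty")
    index = {s: i for i, s in enumerate(network.nodes)}
    in_a = np.zeros(network.n_nodes, bool)
    in_b = np.zeros(network.n_nodes, bool)
    in_a[[index[s] for s in set_a if s in index]] = True
    in_b[[index[s] for s in set_b if s in index]] = True
    hit = (in_a[network.u] & in_b[network.v]) | (in_a[network.v] & in_b[network.u])
    nodes = np.asarray(network.nodes)
    edges = pd.DataFrame(
        {"SYMBOL_A": nodes[network.u[hit]], "SYMBOL_B": nodes[network.v[hit]],
         "EVIDENCE_TYPE": network.evidence[hit]}
    )
    return int(hit.sum()), edges


def bootstrap_null(
    network: PpiNetwork, n_a: int, n_b: int, n_shared: int, n_iterations: int, seed: int = 0
) -> np.ndarray:
    """Null distribution of the between-set count: each iteration draws
    n_a + n_b - n_shared distinct nodes uniformly from the network universe,
    assigns n_shared to both sets and the rest exclusively."""
    if n_shared > min(n_a, n_b):
        raise ValueError("shared members cannot exceed either set size")
    if n_b > n_a:  # canonical order: the count is symmetric, so swapping
        n_a, n_b = n_b, n_a  # labels must not change the null stream
    total = n_a + n_b - n_shared
    if total > network.n_nodes:
        raise ValueError(f"universe of {network.n_nodes} nodes too small for {total} draws")
    rng = stage_rng(seed, "ppi-bootstrap")
    counts = np.empty(n_iterations, dtype=np.int64)
    in_a = np.zeros(network.n_nodes, bool)
    in_b = np.zeros(network.n_nodes, bool)
    u, v = network.u, network.v
    for it in range(n_iterations):
        draw = rng.choice(network.n_nodes, size=total, replace=False)
        in_a[:] = False
        in_b[:] = False
        in_a[draw[:n_a]] = True  # first n_shared of these are the shared block
        in_b[draw[:n_shared]] = True
        in_b[draw[n_a:]] = True
        counts[it] = np.count_nonzero((in_a[u] & in_b[v]) | (in_a[v] & in_b[u]))
    return counts


def empirical_p(s0: int, null_counts: np.ndarray) -> tuple[float, float, bool]:
    """Exactly the printed formula: p = (1 + sum I(s_i >= s0)) / (N + 1),
    ties counted in the tail; fold = s0 / mean(null)."""
    null_counts = np.asarray(null_counts)
    n = len(null_counts)
    if n < 1:
        raise ValueError("need at least one null count")
    p = (1 + int(np.sum(null_counts >= s0))) / (n + 1)
    mean_null = float(null_counts.mean())
    if mean_null == 0:
        return float(p), float("inf"), True
    return float(p), s0 / mean_null, False


def ppi_bootstrap_test(
    network: PpiNetwork, set_a, set_b, n_iterations: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """End-to-end constrained bootstrap: set members absent from the network
    are dropped before sizing (with a log line), mirroring the 404-of-407 /
    43-of-44 adjustment."""
    present = set(network.nodes)
    a = sorted(set(set_a) & present)
    b = sorted(set(set_b) & present)
    dropped = (len(set(set_a)) - len(a)) + (len(set(set_b)) - len(b))
    if dropped:
        log.info("ppi_bootstrap_test: dropped %d set members absent from the network", dropped)
    shared = len(set(a) & set(b))
    s0, _ = count_between(network, a, b)
    null = bootstrap_null(network, len(a), len(b), shared, n_iterations, seed)
    p, fold, inf_flag = empirical_p(s0, null)
    return BootstrapResult(
        s0=s0, null_counts=null, n_iterations=n_iterations, p=p, fold=fold, seed=seed,
        fold_infinite=inf_flag,
    )


def fold_enrichment_counts(k: int, n: int, K: int, N_bg: int) -> SetEnrichmentResult:
    """fold = (k/n)/(K/N_bg); one-sided hypergeometric upper tail for X >= k
    with parameters (N_bg, K, n); Fisher exact on the 2x2 table."""
    if min(n, K, N_bg) <= 0:
        raise ValueError("set sizes and background must be positive")
    if N_bg < K:
        raise ValueError("background smaller than the annotation set")
    if k > min(n, K):
        raise ValueError("hits exceed the smaller of target and annotation size")
    fold = (k / n) / (K / N_bg)
    hyper_p = float(stats.hypergeom.sf(k - 1, N_bg, K, n))
    table = [[k, n - k], [K - k, N_bg - K - (n - k)]]
    fisher_p = float(stats.fisher_exact(table, alternative="greater")[1])
    return SetEnrichmentResult(k=k, n=n, K=K, N_bg=N_bg, fold=fold, hypergeom_p=hyper_p, fisher_p=fisher_p)


def set_fold_enrichment(target_genes, annotation_set, background_size: int) -> SetEnrichmentResult:
    """Enrichment of an annotation set within a target gene list against an
    explicit background size (never inferred: published analyses use
    different backgrounds in different places)."""
    target = set(target_genes)
    annot = set(annotation_set)
    return fold_enrichment_counts(len(target & annot), len(target), len(annot), int(background_size))
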
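"""Signed Spearman co-occurrence networks and their robustness.

A network is built per sample group: taxa passing a prevalence /
mean-abundance filter become nodes, and an edge joins two taxa whenever
their Spearman correlation across the group's samples is strong
(|rho| strictly above the threshold, default 0.8) and significant
(p strictly below the threshold, default 0.05, unadjusted by default).
Edges keep the correlation sign; "negative edges" are read ecologically
as potential competition or exclusion.

Community structure is a modularity-maximizing partition of the
|rho|-weighted edge set; modules below a minimum size stay unlabeled.
Robustness is quantified by natural connectivity — the logarithm of the
average eigenvalue exponential of the (binary) adjacency matrix, a
spectral count of closed walks — tracked while random fractions of
nodes are removed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import spearmanr

__all__ = [
    "NetworkParams",
    "CooccurrenceNetwork",
    "ModulePartition",
    "RobustnessCurve",
    "filter_taxa",
    "spearman_matrix",
    "build_network",
    "negative_edge_ratio",
    "detect_modules",
    "natural_connectivity",
    "robustness_curve",
]


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p-values


@lru_cache(maxsize=None)
def _exact_null_rho(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! rank permutations (no ties)."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return np.sort(np.abs(rho))


def _exact_p(abs_rho: float, n: int) -> float:
    null = _exact_null_rho(n)
    # two-sided: share of permutations at least as extreme in magnitude
    idx = np.searchsorted(null, abs_rho - 1e-12, side="left")
    return float((null.size - idx) / null.size)


def spearman_matrix(
    rel_abund: pd.DataFrame, exact_max_n: int = 9
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p across samples.

    Rho uses average ranks (tie-corrected). P-values come from the
    t-distribution approximation, replaced by the exact permutation null
    for pairs of tie-free vectors when the group has at most
    ``exact_max_n`` samples (the exact null assumes distinct ranks).
    Constant taxa yield undefined correlations: their pairs are excluded
    (rho NaN, p 1) with a warning.
    """
    n_samples = rel_abund.shape[1]
    if n_samples < 4:
        raise ValueError("need at least 4 samples for correlation screening")
    if n_samples < 6:
        warnings.warn(
            f"only {n_samples} samples: correlation estimates are unstable",
            stacklevel=2,
        )
    data = rel_abund.to_numpy()
    constant = np.ptp(data, axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa excluded from correlation",
            stacklevel=2,
        )
    res = spearmanr(data.T)
    rho = np.atleast_2d(res.statistic).astype(float)
    pval = np.atleast_2d(res.pvalue).astype(float)
    if rho.shape == (1, 1):  # scipy collapses the 2-taxon case to scalars
        r, p = float(rho[0, 0]), float(pval[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
        pval = np.array([[0.0, p], [p, 0.0]])
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(pval, 0.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    pval[constant, :] = 1.0
    pval[:, constant] = 1.0
    if n_samples <= exact_max_n:
        tie_free = np.array(
            [np.unique(row).size == n_samples for row in data], dtype=bool
        )
        tie_free &= ~constant
        idx = np.flatnonzero(tie_free)
        for i, j in itertools.combinations(idx, 2):
            p = _exact_p(abs(rho[i, j]), n_samples)
            pval[i, j] = pval[j, i] = p
    taxa = rel_abund.index
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(pval, index=taxa, columns=taxa),
    )


# ---------------------------------------------------------------------------
# Network construction


@dataclass(frozen=True)
class NetworkParams:
    """Construction parameters of a co-occurrence network."""

    rho_threshold: float = 0.8
    p_threshold: float = 0.05
    p_adjust: bool = False
    min_prevalence: int = 3
    min_mean_abundance: float = 1e-4

    def validate(self) -> None:
        if not 0 < self.rho_threshold <= 1:
            raise ValueError(f"rho_threshold must be in (0, 1]: {self.rho_threshold}")
        if not 0 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0, 1]: {self.p_threshold}")
        if self.min_prevalence < 0 or self.min_mean_abundance < 0:
            raise ValueError("filter settings must be nonnegative")


@dataclass
class CooccurrenceNetwork:
    """Signed, weighted undirected co-occurrence graph for one group."""

    graph: nx.Graph
    params: NetworkParams
    group: str | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node1": u, "node2": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "rho", "p", "sign"])


def filter_taxa(
    rel_abund: pd.DataFrame,
    min_prevalence: int = 3,
    min_mean_abundance: float = 1e-4,
) -> pd.DataFrame:
    """Keep taxa present in >= ``min_prevalence`` samples of the group with
    mean relative abundance >= ``min_mean_abundance``.

    Spearman correlation of near-constant vectors at half a dozen samples
    is meaningless; the filter removes them before screening.
    """
    prevalence = (rel_abund > 0).sum(axis=1)
    mean_ab = rel_abund.mean(axis=1)
    keep = (prevalence >= min_prevalence) & (mean_ab >= min_mean_abundance)
    return rel_abund.loc[keep]


def build_network(
    rho: pd.DataFrame,
    pval: pd.DataFrame,
    params: NetworkParams | None = None,
    group: str | None = None,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrices into a signed network.

    An edge requires |rho| strictly greater than ``rho_threshold`` AND p
    strictly below ``p_threshold`` (both boundaries excluded). With
    ``p_adjust`` the off-diagonal p-values are BH-adjusted first. An
    empty network is returned with a warning, not an error.
    """
    from .diversity import adjust_bh

    params = params or NetworkParams()
    params.validate()
    taxa = rho.index
    r = rho.to_numpy()
    p = pval.to_numpy()
    iu = np.triu_indices(len(taxa), k=1)
    p_edge = p[iu]
    if params.p_adjust:
        p_edge = adjust_bh(p_edge)
    r_edge = r[iu]
    with np.errstate(invalid="ignore"):
        keep = (np.abs(r_edge) > params.rho_threshold) & (p_edge < params.p_threshold)
    keep &= ~np.isnan(r_edge)
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for i, j, rr, pp in zip(
        iu[0][keep], iu[1][keep], r_edge[keep], p_edge[keep]
    ):
        g.add_edge(
            taxa[i],
            taxa[j],
            rho=float(rr),
            p=float(pp),
            sign=1 if rr > 0 else -1,
            weight=abs(float(rr)),
        )
    if g.number_of_edges() == 0:
        warnings.warn(f"network {group!r} has no edges", stacklevel=2)
    return CooccurrenceNetwork(graph=g, params=params, group=group)


def negative_edge_ratio(net: CooccurrenceNetwork) -> float:
    """Fraction of edges with negative correlation; NaN for an edgeless net."""
    signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
    if not signs:
        warnings.warn("negative-edge ratio undefined for an edgeless network",
                      stacklevel=2)
        return float("nan")
    return signs.count(-1) / len(signs)


# ---------------------------------------------------------------------------
# Modules


@dataclass
class ModulePartition:
    """Node-to-module assignment; small modules carry a null id (NaN)."""

    assignment: pd.Series  # node -> module id (int) or NaN for unlabeled
    modularity: float
    seed: int
    min_module_size: int

    def members(self, module_id: int) -> list:
        return self.assignment.index[self.assignment == module_id].tolist()

    @property
    def module_ids(self) -> list[int]:
        ids = self.assignment.dropna().unique()
        return sorted(int(i) for i in ids)

    def module_of(self, node) -> int | None:
        if node not in self.assignment.index:
            return None
        val = self.assignment.loc[node]
        return None if pd.isna(val) else int(val)


def detect_modules(
    net: CooccurrenceNetwork, seed: int = 0, min_module_size: int = 5
) -> ModulePartition:
    """Greedy modularity-maximizing partition of the |rho|-weighted graph.

    The greedy agglomeration is deterministic; ``seed`` is recorded for
    provenance (and for future stochastic detectors). Communities smaller
    than ``min_module_size`` remain unlabeled. Module ids are assigned by
    content (descending size, then lexicographically smallest member) so
    that identical networks always yield identical labels; modules should
    be identified across runs by membership, never by ordinal id.
    """
    g = net.graph
    assignment = pd.Series(np.nan, index=pd.Index(net.nodes, name="taxon_id"))
    if g.number_of_edges() == 0:
        return ModulePartition(assignment, 0.0, seed, min_module_size)
    communities = nx.algorithms.community.greedy_modularity_communities(
        g, weight="weight"
    )
    q = nx.algorithms.community.modularity(g, communities, weight="weight")
    big = [sorted(c) for c in communities if len(c) >= min_module_size]
    big.sort(key=lambda c: (-len(c), c[0]))
    for mid, members in enumerate(big, start=1):
        assignment.loc[members] = mid
    return ModulePartition(assignment, float(q), seed, min_module_size)


# ---------------------------------------------------------------------------
# Natural connectivity and robustness


def natural_connectivity(graph_or_nodes, weighted: bool = False) -> float:
    """Natural connectivity of a graph (or node-induced subgraph).

    ``ln((1/N) * sum_i exp(lambda_i))`` over the eigenvalues of the
    adjacency matrix of the current (sub)graph, N its node count. The
    adjacency is binary by default (robustness-literature convention);
    ``weighted=True`` uses |rho| edge weights instead. An edgeless graph
    has value 0.
    """
    if isinstance(graph_or_nodes, CooccurrenceNetwork):
        g = graph_or_nodes.graph
    else:
        g = graph_or_nodes
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("natural connectivity undefined for an empty graph")
    weight = "weight" if weighted else None
    a = nx.to_numpy_array(g, weight=weight)
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - math.log(n))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30,
                     0.35, 0.40, 0.45, 0.50, 0.55, 0.60)


@dataclass
class RobustnessCurve:
    """Natural connectivity vs fraction of nodes randomly removed."""

    fractions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_reps: int
    seed: int
    intact: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction_removed": self.fractions, "mean": self.mean, "sd": self.sd}
        )

    @property
    def auc(self) -> float:
        """Trapezoidal area under the mean curve (incl. the intact point)."""
        x = np.concatenate([[0.0], self.fractions])
        y = np.concatenate([[self.intact], self.mean])
        return float(np.trapezoid(y, x))


def robustness_curve(
    net: CooccurrenceNetwork | nx.Graph,
    fractions=DEFAULT_FRACTIONS,
    n_reps: int = 50,
    seed: int = 0,
    weighted: bool = False,
) -> RobustnessCurve:
    """Mean +/- sd natural connectivity under random node removal.

    For each fraction f, ``round(f * N)`` nodes (round half away from
    zero, so curves are bit-reproducible) are removed uniformly at
    random and natural connectivity is recomputed on the induced
    subgraph, averaged over ``n_reps`` removals.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions <= 0) | (fractions >= 1)):
        raise ValueError("fractions must lie strictly in (0, 1)")
    nodes = np.array(list(g.nodes))
    n = nodes.size
    removals = [_round_half_away(f * n) for f in fractions]
    if any(k >= n for k in removals):
        raise ValueError("a fraction would remove every node")
    rng = np.random.default_rng(seed)
    means = np.empty(fractions.size)
    sds = np.empty(fractions.size)
    for fi, k in enumerate(removals):
        vals = np.empty(n_reps)
        for rep in range(n_reps):
            keep = rng.permutation(n)[k:]
            sub = g.subgraph(nodes[keep])
            vals[rep] = natural_connectivity(sub, weighted=weighted)
        means[fi] = vals.mean()
        sds[fi] = vals.std(ddof=0)
    return RobustnessCurve(
        fractions=fractions,
        mean=means,
        sd=sds,
        n_reps=n_reps,
        seed=seed,
        intact=natural_connectivity(g, weighted=weighted),
    )
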
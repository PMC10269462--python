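"""Module eigengenes, trait coupling and hub taxa.

A module's activity across samples is summarized by its *eigengene*: the
first principal component of the member taxa's standardized relative
abundance profiles, oriented to correlate positively with the module's
mean standardized abundance. Eigengenes are then correlated (Pearson by
default) with plant traits and soil enzyme activities; hub (keystone
candidate) taxa are nodes in the top fraction of the network by both
degree and betweenness centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diversity import adjust_bh
from .network import CooccurrenceNetwork, ModulePartition

__all__ = [
    "Eigengene",
    "module_eigengene",
    "all_module_eigengenes",
    "ModuleTraitCorrelation",
    "correlate_modules",
    "hub_nodes",
]


@dataclass
class Eigengene:
    """First-PC summary of a module's abundance profile."""

    module_id: int
    scores: pd.Series  # per-sample, zero mean
    variance_explained: float
    oriented_flip: bool  # True if the raw first PC was sign-flipped


def module_eigengene(
    rel_abund: pd.DataFrame, members, module_id: int = 0
) -> Eigengene:
    """Eigengene of one module from member rows of a relative-abundance table.

    Member profiles are standardized to zero mean / unit variance across
    samples (so the result is invariant to rescaling any taxon), then the
    first principal component score vector over samples is extracted by
    SVD. The sign is fixed so the eigengene correlates positively with
    the members' mean standardized abundance.
    """
    members = [m for m in members if m in rel_abund.index]
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 member taxa")
    if rel_abund.shape[1] < 3:
        raise ValueError("a module eigengene needs at least 3 samples")
    x = rel_abund.loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    constant = np.ptp(x, axis=1) == 0  # exact constancy, not sd rounding
    if constant.any():
        dropped = [m for m, c in zip(members, constant) if c]
        warnings.warn(f"constant member profiles dropped: {dropped}", stacklevel=2)
        x = x[~constant]
        members = [m for m, c in zip(members, constant) if not c]
        if len(members) < 2:
            raise ValueError("module collapsed below 2 usable members")
        sd = sd[~constant]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples x taxa; first left-singular vector spans the score space
    u, s, _ = np.linalg.svd(z.T, full_matrices=False)
    scores = u[:, 0] * s[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    flip = False
    if np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
        flip = True
    return Eigengene(
        module_id=module_id,
        scores=pd.Series(scores - scores.mean(), index=rel_abund.columns),
        variance_explained=var_explained,
        oriented_flip=flip,
    )


def all_module_eigengenes(
    rel_abund: pd.DataFrame, partition: ModulePartition
) -> dict[int, Eigengene]:
    """Eigengenes for every labeled module of a partition."""
    out = {}
    for mid in partition.module_ids:
        out[mid] = module_eigengene(rel_abund, partition.members(mid), module_id=mid)
    return out


@dataclass
class ModuleTraitCorrelation:
    """Module x variable correlation matrices (r, raw p, BH-adjusted p)."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame  # complete sample pairs used per cell
    method: str

    def to_long(self) -> pd.DataFrame:
        rows = []
        for mid in self.r.index:
            for var in self.r.columns:
                rows.append(
                    {
                        "module": mid,
                        "variable": var,
                        "r": self.r.loc[mid, var],
                        "p": self.p.loc[mid, var],
                        "p_adj": self.p_adj.loc[mid, var],
                        "n": self.n.loc[mid, var],
                    }
                )
        return pd.DataFrame(rows)


def correlate_modules(
    eigengenes: dict[int, Eigengene],
    variables: pd.DataFrame,
    method: str = "pearson",
) -> ModuleTraitCorrelation:
    """Correlate each module eigengene with each trait/enzyme variable.

    Missing values are deleted pairwise and the usable sample count is
    reported per cell. A zero-variance variable yields an undefined
    (NaN) correlation, reported as missing. BH adjustment is applied
    across the full module x variable matrix.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method: {method!r}")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    mids = sorted(eigengenes)
    r = pd.DataFrame(np.nan, index=mids, columns=variables.columns)
    p = r.copy()
    n = pd.DataFrame(0, index=mids, columns=variables.columns)
    for mid in mids:
        scores = eigengenes[mid].scores
        for var in variables.columns:
            joint = pd.concat(
                [scores, variables[var].reindex(scores.index)], axis=1
            ).dropna()
            n.loc[mid, var] = len(joint)
            if len(joint) < 3:
                continue
            x, y = joint.iloc[:, 0], joint.iloc[:, 1]
            if y.nunique() < 2:
                warnings.warn(f"variable {var!r} has zero variance", stacklevel=2)
                continue
            res = corr(x, y)
            r.loc[mid, var] = float(res.statistic)
            p.loc[mid, var] = float(res.pvalue)
    p_adj = pd.DataFrame(
        adjust_bh(p.to_numpy().ravel()).reshape(p.shape),
        index=p.index,
        columns=p.columns,
    )
    return ModuleTraitCorrelation(r=r, p=p, p_adj=p_adj, n=n, method=method)


def hub_nodes(
    net: CooccurrenceNetwork,
    partition: ModulePartition | None = None,
    top_fraction: float = 0.1,
) -> pd.DataFrame:
    """Per-node degree, normalized betweenness and hub flag.

    A hub is a node ranking in the top ``top_fraction`` of the network
    by BOTH degree and betweenness centrality (shortest-path counting
    on the unweighted graph). Cutoffs are computed among connected
    nodes — isolated taxa are never hubs and must not drag the decile
    boundary to zero. Ties at the cutoff keep all tied nodes.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    g = net.graph
    nodes = list(g.nodes)
    degree = pd.Series(dict(g.degree()), dtype=float)
    betweenness = pd.Series(nx.betweenness_centrality(g, normalized=True))
    out = pd.DataFrame(
        {
            "degree": degree.reindex(nodes).astype(int),
            "betweenness": betweenness.reindex(nodes),
        },
        index=pd.Index(nodes, name="taxon_id"),
    )
    if partition is not None:
        out.insert(0, "module", [partition.module_of(v) for v in nodes])
    connected = out["degree"] > 0
    if not connected.any():
        out["hub"] = False
        return out
    k = max(1, int(np.ceil(top_fraction * int(connected.sum()))))
    deg_cut = out.loc[connected, "degree"].nlargest(k).iloc[-1]
    bet_cut = out.loc[connected, "betweenness"].nlargest(k).iloc[-1]
    out["hub"] = (
        connected & (out["degree"] >= deg_cut) & (out["betweenness"] >= bet_cut)
    )
    return out
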
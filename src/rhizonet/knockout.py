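"""In-silico taxon knockout and module-persistence testing.

The key causal probe of the analysis: delete a genus from the count
table (``remove``) or scale its abundance in coated samples down to the
control level (``reduce``), rebuild the co-occurrence network with the
same parameters and seeds, and ask whether the module that contained
the genus persists — measured as the proportion of the original
module's nodes recovered inside the best-matching rebuilt module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io as rio
from .network import (
    CooccurrenceNetwork,
    ModulePartition,
    NetworkParams,
    build_network,
    detect_modules,
    filter_taxa,
    spearman_matrix,
)

__all__ = [
    "knockout_remove",
    "knockout_reduce",
    "match_modules",
    "KnockoutResult",
    "ModuleMatch",
    "knockout_experiment",
]


def knockout_remove(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, genus: str
) -> pd.DataFrame:
    """Drop every OTU annotated to ``genus``; samples are untouched.

    An absent genus is a warned no-op. Idempotent.
    """
    members = rio.genus_members(taxonomy, genus)
    members = [m for m in members if m in counts.index]
    if not members:
        warnings.warn(f"genus {genus!r} absent; remove is a no-op", stacklevel=2)
        return counts.copy()
    return counts.drop(index=members)


def _genus_mean_relabund(counts: pd.DataFrame, members, samples) -> float:
    sub = counts[samples]
    totals = sub.sum(axis=0)
    return float((sub.loc[members].sum(axis=0) / totals).mean())


def knockout_reduce(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    genus: str,
    metadata: pd.DataFrame,
    coated_label: str = "coated",
    control_label: str = "control",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Scale the genus in coated samples to the control's mean level.

    All member OTUs share one common scaling factor (preserving
    within-genus composition), chosen so that the genus's mean relative
    abundance over coated samples equals its mean over control samples
    after rescaling (sample totals shrink with the genus, so the factor
    is solved numerically, not the naive ratio of means). Scaled counts
    are rounded to integers; zeros stay zero; control samples are never
    modified. A genus absent from the controls is zeroed in the coated
    samples (factor 0), with a log message.
    """
    members = rio.genus_members(taxonomy, genus)
    members = [m for m in members if m in counts.index]
    if not members:
        warnings.warn(f"genus {genus!r} absent; reduce is a no-op", stacklevel=2)
        return counts.copy()
    treatments = metadata.loc[counts.columns, treatment_col]
    coated = counts.columns[treatments == coated_label]
    control = counts.columns[treatments == control_label]
    if len(coated) == 0 or len(control) == 0:
        raise ValueError("both coated and control samples are required")
    target = _genus_mean_relabund(counts, members, control)
    out = counts.copy()
    g = counts.loc[members, coated].to_numpy(dtype=float)
    rest = counts[coated].sum(axis=0).to_numpy() - g.sum(axis=0)

    def mean_rel(alpha: float) -> float:
        scaled = alpha * g.sum(axis=0)
        return float(np.mean(scaled / (rest + scaled)))

    if target <= 0:
        warnings.warn(
            f"genus {genus!r} absent from control samples; zeroed in coated",
            stacklevel=2,
        )
        alpha = 0.0
    elif mean_rel(1.0) <= target:
        alpha = 1.0  # already at or below control level; leave untouched
    else:
        alpha = brentq(lambda a: mean_rel(a) - target, 0.0, 1.0)
    out.loc[members, coated] = np.rint(alpha * g).astype(np.int64)
    return out


@dataclass
class ModuleMatch:
    """Best-overlap match of a target node set against a rebuilt partition."""

    best_module: int | None
    shared_proportion: float
    jaccard: float
    shared_nodes: list = field(default_factory=list)


def match_modules(
    target_nodes,
    rebuilt: ModulePartition,
    rebuilt_network_nodes=None,
) -> ModuleMatch:
    """Proportion of target-module nodes recovered in the best rebuilt module.

    The target set is first restricted to nodes present in the rebuilt
    network (so removed taxa drop out of the denominator). For each
    labeled rebuilt module the shared-node proportion
    ``|target & module| / |target|`` is computed; the maximizing module
    wins, ties broken by smaller module id. Jaccard overlap is reported
    alongside. An empty rebuilt partition scores 0.
    """
    target = list(dict.fromkeys(target_nodes))
    if not target:
        raise ValueError("target module is empty")
    if rebuilt_network_nodes is not None:
        present = set(rebuilt_network_nodes)
        target = [t for t in target if t in present]
    if not target:
        return ModuleMatch(None, 0.0, 0.0)
    target_set = set(target)
    best = None
    for mid in rebuilt.module_ids:  # ascending ids: ties keep the smaller id
        members = set(rebuilt.members(mid))
        shared = target_set & members
        prop = len(shared) / len(target_set)
        jac = len(shared) / len(target_set | members)
        if best is None or prop > best.shared_proportion:
            best = ModuleMatch(mid, prop, jac, sorted(shared))
    return best if best is not None else ModuleMatch(None, 0.0, 0.0)


@dataclass
class KnockoutResult:
    """Outcome of a remove/reduce knockout of one genus."""

    genus: str
    mode: str  # "remove" or "reduce"
    network: CooccurrenceNetwork
    partition: ModulePartition
    match: ModuleMatch
    persists: bool
    match_threshold: float
    target_module: list = field(default_factory=list)  # pre-knockout nodes
    shared_hubs: list = field(default_factory=list)


def _rebuild(
    counts: pd.DataFrame,
    samples,
    params: NetworkParams,
    seed: int,
    min_module_size: int,
    group: str,
) -> tuple[CooccurrenceNetwork, ModulePartition]:
    rel = rio.to_relative_abundance(counts[list(samples)])
    rel = filter_taxa(rel, params.min_prevalence, params.min_mean_abundance)
    rho, p = spearman_matrix(rel)
    net = build_network(rho, p, params, group=group)
    part = detect_modules(net, seed=seed, min_module_size=min_module_size)
    return net, part


def knockout_experiment(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: pd.DataFrame,
    genus: str,
    samples=None,
    params: NetworkParams | None = None,
    seed: int = 0,
    min_module_size: int = 5,
    match_threshold: float = 0.5,
    modes: tuple = ("remove", "reduce"),
    coated_label: str = "coated",
    control_label: str = "control",
    treatment_col: str = "treatment",
    target_module: list | None = None,
) -> dict[str, KnockoutResult]:
    """Run the full knockout protocol against a genus.

    First the intact analysis is run on ``samples`` (default: the coated
    samples) to locate the target module — the labeled module containing
    the genus. Then, per mode, the table is perturbed, the network and
    partition are rebuilt with identical parameters and seed, and the
    target is matched by shared-node proportion; persistence is declared
    when the proportion reaches ``match_threshold``. Hubs of the target
    module recovered in the matched module are reported alongside the
    verdict (not folded into it).

    A precomputed ``target_module`` node list can be supplied to skip
    the intact run (e.g. when it is already available from a pipeline
    stage).
    """
    params = params or NetworkParams()
    if samples is None:
        samples = metadata.index[metadata[treatment_col] == coated_label]
    samples = [s for s in samples if s in counts.columns]
    members = [m for m in rio.genus_members(taxonomy, genus) if m in counts.index]
    if not members:
        raise ValueError(f"genus {genus!r} not present in the count table")

    if target_module is None:
        net0, part0 = _rebuild(
            counts, samples, params, seed, min_module_size, group="intact"
        )
        target_ids = {part0.module_of(m) for m in members}
        target_ids.discard(None)
        if not target_ids:
            raise ValueError(
                f"genus {genus!r} belongs to no labeled module in the intact network"
            )
        tid = min(target_ids)
        target_module = part0.members(tid)
        from .modules import hub_nodes

        hub_table = hub_nodes(net0, part0)
        target_hubs = set(hub_table.index[hub_table["hub"]]) & set(target_module)
    else:
        target_hubs = set()

    results: dict[str, KnockoutResult] = {}
    for mode in modes:
        if mode == "remove":
            perturbed = knockout_remove(counts, taxonomy, genus)
            target = [t for t in target_module if t not in members]
        elif mode == "reduce":
            perturbed = knockout_reduce(
                counts,
                taxonomy,
                genus,
                metadata,
                coated_label=coated_label,
                control_label=control_label,
                treatment_col=treatment_col,
            )
            target = list(target_module)
        else:
            raise ValueError(f"unknown knockout mode: {mode!r}")
        net, part = _rebuild(
            perturbed, samples, params, seed, min_module_size, group=mode
        )
        match = match_modules(target, part, rebuilt_network_nodes=net.nodes)
        shared_hubs = sorted(target_hubs & set(match.shared_nodes))
        results[mode] = KnockoutResult(
            genus=genus,
            mode=mode,
            network=net,
            partition=part,
            match=match,
            persists=match.shared_proportion >= match_threshold,
            match_threshold=match_threshold,
            target_module=list(target_module),
            shared_hubs=shared_hubs,
        )
    return results
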
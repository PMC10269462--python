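"""Simulation-based validation suites for the pipeline.

Each function here runs one end-to-end statistical check of the
analysis on data from the synthetic generator — oracle agreement for
the spectral and centrality primitives, null calibration of the tests,
planted-structure recovery, and the knockout specificity experiment —
and returns the measured quantities. The suites are what the package's
acceptance checks and its validation report are built from.

Scenario sizes are fixed here, chosen from the power analysis in the
methods documentation (e.g. correlation-threshold networks need enough
samples per group for the |rho| > 0.8 rule to have a controlled
false-edge rate), and are part of the suites' definitions.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import io as rio
from .diversity import (
    alpha_diversity,
    alpha_diversity_tests,
    bray_curtis,
    compare_groups,
    permanova,
)
from .knockout import knockout_remove, match_modules
from .modules import correlate_modules, module_eigengene
from .network import (
    NetworkParams,
    build_network,
    detect_modules,
    filter_taxa,
    natural_connectivity,
    negative_edge_ratio,
    spearman_matrix,
)
from .synthetic import (
    ModuleSpec,
    SyntheticScenario,
    TraitSpec,
    generate_counts,
    planted_truth,
)

__all__ = [
    "natural_connectivity_oracle",
    "betweenness_oracle",
    "spearman_oracle",
    "null_calibration",
    "planted_module_recovery",
    "trait_recovery",
    "knockout_specificity",
    "negative_edge_direction",
    "diversity_neutrality",
]


# ---------------------------------------------------------------------------
# Oracle equivalence


def natural_connectivity_oracle(
    n_graphs: int = 200, max_n: int = 20, seed: int = 0
) -> dict:
    """Compare the eigenvalue formula against ln(trace(expm(A))/N).

    Random Erdos-Renyi graphs; returns the maximum absolute discrepancy
    between the two routes over all graphs.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        p = float(rng.uniform(0.05, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        a = nx.to_numpy_array(g)
        oracle = float(np.log(np.trace(expm(a)) / n))
        ours = natural_connectivity(g)
        worst = max(worst, abs(ours - oracle))
    return {"max_abs_error": worst, "n_graphs": n_graphs}


def _brute_force_betweenness(g: nx.Graph) -> dict:
    """Betweenness by exhaustive simple-path enumeration (tiny graphs only)."""
    nodes = list(g.nodes)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            raw[v] += through / len(geodesics)
    scale = (n - 1) * (n - 2) / 2.0
    return {v: (raw[v] / scale if scale > 0 else 0.0) for v in nodes}


def betweenness_oracle(n_graphs: int = 40, seed: int = 0) -> dict:
    """Shortest-path betweenness vs exhaustive path enumeration (n <= 8)."""
    rng = np.random.default_rng(seed)
    graphs = [nx.star_graph(5), nx.cycle_graph(6), nx.path_graph(5)]
    for _ in range(n_graphs):
        n = int(rng.integers(4, 9))
        p = float(rng.uniform(0.25, 0.9))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    worst = 0.0
    for g in graphs:
        oracle = _brute_force_betweenness(g)
        ours = nx.betweenness_centrality(g, normalized=True)
        for v in g.nodes:
            worst = max(worst, abs(ours[v] - oracle[v]))
    return {"max_abs_error": worst, "n_graphs": len(graphs)}


def spearman_oracle(n_vectors: int = 1000, seed: int = 0) -> dict:
    """Spearman rho vs the rank-difference formula on tie-free vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        n = int(rng.integers(5, 31))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        frame = pd.DataFrame([x, y], index=["a", "b"],
                             columns=[f"s{i}" for i in range(n)])
        rho, _ = spearman_matrix(frame)
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        oracle = 1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))
        worst = max(worst, abs(rho.loc["a", "b"] - oracle))
    return {"max_abs_error": worst, "n_vectors": n_vectors}


# ---------------------------------------------------------------------------
# Statistical calibration under the null


def null_calibration(
    n_reps: int = 500, permutations: int = 999, seed: int = 0
) -> dict:
    """Type-I error of PERMANOVA and the rank test on null communities.

    Each replicate draws a structure-free two-group community (12
    samples per group: large enough that the rank test's discrete exact
    level is replaced by the near-nominal tie-corrected approximation),
    then tests coated vs control at alpha = 0.05 on Bray-Curtis
    composition (PERMANOVA) and on Shannon diversity (rank-sum).
    Returns the two rejection rates, which should sit near 0.05.
    """
    ss = np.random.SeedSequence(seed)
    rej_perm = 0
    rej_rank = 0
    for child in ss.spawn(n_reps):
        state = child.generate_state(2)
        scenario = SyntheticScenario.null(
            seed=int(state[0] % 2**31),
            n_taxa=100,
            n_samples_per_group=12,
            groups=(("maize", "coated"), ("maize", "control")),
        )
        counts, _, meta = generate_counts(scenario)
        rel = rio.to_relative_abundance(counts)
        dist = bray_curtis(rel)
        res = permanova(
            dist, meta["treatment"], permutations=permutations,
            seed=int(state[1] % 2**31),
        )
        if res.p_value <= 0.05:
            rej_perm += 1
        alpha = alpha_diversity(counts)
        coated = alpha.loc[meta.index[meta["treatment"] == "coated"], "shannon"]
        control = alpha.loc[meta.index[meta["treatment"] == "control"], "shannon"]
        _, p = compare_groups(coated, control)
        if p <= 0.05:
            rej_rank += 1
    return {
        "permanova_rejection_rate": rej_perm / n_reps,
        "rank_test_rejection_rate": rej_rank / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Planted-structure recovery


def _coated_network(counts, meta, params, min_module_size=5, seed=0):
    samples = meta.index[meta["treatment"] == "coated"]
    rel = rio.to_relative_abundance(counts[list(samples)])
    rel = filter_taxa(rel, params.min_prevalence, params.min_mean_abundance)
    rho, p = spearman_matrix(rel)
    net = build_network(rho, p, params, group="coated")
    part = detect_modules(net, seed=seed, min_module_size=min_module_size)
    return net, part


def planted_module_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    """Recovery of a 15-member planted module (loading 0.9, 30/group).

    The community also carries two background modules and coupled pairs,
    so the planted module holds a minority of the network's edges — the
    realistic regime; a module containing nearly every edge of its graph
    is split by any modularity-maximizing detector (the resolution
    degeneracy). The coated-group network is built and partitioned; the
    detected module overlapping the planted membership best is scored by
    node precision and recall against the generator truth. Mean values
    over replicates are returned.
    """
    ss = np.random.SeedSequence(seed)
    params = NetworkParams()
    precisions, recalls = [], []
    for child in ss.spawn(n_reps):
        scenario = SyntheticScenario(
            n_taxa=200,
            n_samples_per_group=30,
            groups=(("maize", "coated"), ("maize", "control")),
            module_spec=(
                ModuleSpec(n_members=15, loading=0.9),
                ModuleSpec(n_members=12, loading=0.9),
                ModuleSpec(n_members=12, loading=0.9),
            ),
            n_positive_pairs=20,
            n_baseline_negative_pairs=5,
            competition_strength=0.0,
            trait_spec=(),
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        counts, _, meta = generate_counts(scenario)
        truth = set(planted_truth(scenario)["modules"][0]["members"])
        _, part = _coated_network(counts, meta, params)
        best_p, best_r = 0.0, 0.0
        for mid in part.module_ids:
            members = set(part.members(mid))
            inter = len(members & truth)
            if inter == 0:
                continue
            recall = inter / len(truth)
            precision = inter / len(members)
            if recall > best_r:
                best_p, best_r = precision, recall
        precisions.append(best_p)
        recalls.append(best_r)
    return {
        "mean_precision": float(np.mean(precisions)),
        "mean_recall": float(np.mean(recalls)),
        "n_reps": n_reps,
    }


def trait_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """Eigengene-trait correlation recovery at generating r = 0.8, n = 60.

    One 10-member module in a single 60-sample group; a growth trait is
    coupled to its latent factor at generating correlation +0.8 and a
    disease-style trait at -0.8. The planted members' eigengene is
    correlated with both traits; returns the share of replicates whose
    recovered r is within +/-0.15 of +0.8 and the share with a negative
    recovered disease correlation.
    """
    target_r = 0.8
    noise_sd = 1.5
    coupling = noise_sd * target_r / np.sqrt(1 - target_r**2)
    ss = np.random.SeedSequence(seed)
    within = 0
    sign_ok = 0
    for child in ss.spawn(n_reps):
        scenario = SyntheticScenario(
            n_taxa=60,
            n_samples_per_group=60,
            groups=(("maize", "coated"),),
            module_spec=(ModuleSpec(n_members=10, loading=0.9),),
            n_positive_pairs=0,
            n_baseline_negative_pairs=0,
            competition_strength=0.0,
            trait_spec=(
                TraitSpec("growth", 0, coupling, noise_sd),
                TraitSpec("disease_incidence", 0, -coupling, noise_sd),
            ),
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        counts, _, meta = generate_counts(scenario)
        members = planted_truth(scenario)["modules"][0]["members"]
        rel = rio.to_relative_abundance(counts)
        eig = module_eigengene(rel, members, module_id=1)
        corr = correlate_modules({1: eig}, meta[["growth", "disease_incidence"]])
        r_growth = corr.r.loc[1, "growth"]
        r_disease = corr.r.loc[1, "disease_incidence"]
        if abs(r_growth - target_r) <= 0.15:
            within += 1
        if r_disease < 0:
            sign_ok += 1
    return {
        "growth_r_within_015": within / n_reps,
        "disease_negative_sign_rate": sign_ok / n_reps,
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Knockout specificity


def _knockout_scenario(rep_seed: int) -> SyntheticScenario:
    return SyntheticScenario(
        n_taxa=150,
        n_samples_per_group=40,
        groups=(("maize", "coated"), ("maize", "control")),
        module_spec=(
            ModuleSpec(n_members=5, loading=0.95, focal=True),
            ModuleSpec(n_members=8, loading=0.85),
        ),
        n_positive_pairs=8,
        n_baseline_negative_pairs=2,
        competition_strength=0.0,
        trait_spec=(),
        seed=rep_seed,
    )


def knockout_specificity(n_reps: int = 50, seed: int = 0) -> dict:
    """Does removing the focal genus — and only it — dissolve its module?

    Per replicate a focal-nucleated community is drawn; the intact
    coated network provides the target module containing the focal
    genus. The focal genus and, separately, an abundance-matched random
    non-member genus are removed; the network is rebuilt each time and
    the target matched by shared-node proportion. Returns the rate of
    dissolution (< 0.5) under focal removal and of persistence (>= 0.5)
    under control removal. Replicates where the intact analysis yields
    no labeled focal module count against both rates.
    """
    ss = np.random.SeedSequence(seed)
    params = NetworkParams()
    dissolved = 0
    persisted = 0
    focal_props, control_props = [], []
    for child in ss.spawn(n_reps):
        state = child.generate_state(2)
        scenario = _knockout_scenario(int(state[0] % 2**31))
        counts, tax, meta = generate_counts(scenario)
        truth = planted_truth(scenario)
        focal = truth["focal_taxon"]
        samples = meta.index[meta["treatment"] == "coated"]
        net0, part0 = _coated_network(counts, meta, params)
        mid = part0.module_of(focal)
        if mid is None:
            continue  # no labeled target: counts against both rates below
        target = part0.members(mid)
        genus_focal = tax.loc[focal, "genus"]

        def rebuilt_proportion(genus: str, target_nodes) -> float:
            pruned = knockout_remove(counts, tax, genus)
            rel = rio.to_relative_abundance(pruned[list(samples)])
            rel = filter_taxa(rel, params.min_prevalence, params.min_mean_abundance)
            rho, p = spearman_matrix(rel)
            net = build_network(rho, p, params, group="coated")
            part = detect_modules(net, seed=0, min_module_size=5)
            match = match_modules(target_nodes, part,
                                  rebuilt_network_nodes=net.nodes)
            return match.shared_proportion

        prop_focal = rebuilt_proportion(genus_focal,
                                        [t for t in target if t != focal])
        focal_props.append(prop_focal)
        if prop_focal < 0.5:
            dissolved += 1

        # abundance-matched random non-member genus
        module_members = {m for spec in truth["modules"] for m in spec["members"]}
        rel_all = rio.to_relative_abundance(counts[list(samples)])
        focal_ab = rel_all.loc[focal].mean()
        candidates = rel_all.index.difference(module_members)
        rng = np.random.default_rng(int(state[1] % 2**31))
        pool = (rel_all.loc[candidates].mean(axis=1) - focal_ab).abs().nsmallest(10)
        control_taxon = rng.choice(pool.index.to_numpy())
        prop_control = rebuilt_proportion(tax.loc[control_taxon, "genus"], target)
        control_props.append(prop_control)
        if prop_control >= 0.5:
            persisted += 1
    return {
        "focal_dissolution_rate": dissolved / n_reps,
        "control_persistence_rate": persisted / n_reps,
        "mean_focal_proportion": float(np.mean(focal_props)) if focal_props else 1.0,
        "mean_control_proportion": (
            float(np.mean(control_props)) if control_props else 0.0
        ),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Negative-edge direction and diversity neutrality


def negative_edge_direction(n_sims: int = 100, seed: int = 0) -> dict:
    """Coated vs control negative-edge ratio under coated-only competition.

    Communities with antagonistic pairs active only under coating (plus
    shared positive and baseline negative pairs in both groups) are
    simulated at 20 samples per group; both group networks are built and
    their negative-edge ratios compared. Returns the fraction of
    simulations where the coated ratio exceeds the control ratio.
    """
    ss = np.random.SeedSequence(seed)
    params = NetworkParams()
    higher = 0
    ratios = []
    for child in ss.spawn(n_sims):
        scenario = SyntheticScenario(
            n_taxa=150,
            n_samples_per_group=20,
            groups=(("maize", "coated"), ("maize", "control")),
            competition_strength=1.0,
            trait_spec=(),
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        counts, _, meta = generate_counts(scenario)
        group_ratio = {}
        for treatment in ("coated", "control"):
            samples = meta.index[meta["treatment"] == treatment]
            rel = rio.to_relative_abundance(counts[list(samples)])
            rel = filter_taxa(rel, params.min_prevalence, params.min_mean_abundance)
            rho, p = spearman_matrix(rel)
            net = build_network(rho, p, params, group=treatment)
            group_ratio[treatment] = negative_edge_ratio(net)
        ratios.append(group_ratio)
        if group_ratio["coated"] > group_ratio["control"]:
            higher += 1
    return {
        "coated_exceeds_control_rate": higher / n_sims,
        "mean_coated_ratio": float(np.nanmean([r["coated"] for r in ratios])),
        "mean_control_ratio": float(np.nanmean([r["control"] for r in ratios])),
        "n_sims": n_sims,
    }


def diversity_neutrality(n_reps: int = 200, seed: int = 0) -> dict:
    """Alpha diversity should not differ between coated and control.

    The default scenario enriches the focal genus and rewires
    covariances under coating without a community-wide diversity shift.
    Per replicate, counts are rarefied to the minimum depth and Shannon/
    Pielou/Chao1 are compared between treatments within each crop
    (BH-adjusted rank tests). Returns, per index, the fraction of
    replicates with no significant comparison.
    """
    ss = np.random.SeedSequence(seed)
    non_sig = {"shannon": 0, "pielou": 0, "chao1": 0}
    for child in ss.spawn(n_reps):
        state = child.generate_state(2)
        scenario = SyntheticScenario(seed=int(state[0] % 2**31))
        counts, _, meta = generate_counts(scenario)
        rare = rio.rarefy(counts, seed=int(state[1] % 2**31))
        alpha = alpha_diversity(rare)
        table = alpha_diversity_tests(alpha, meta, group_col="treatment",
                                      within="crop")
        for index_name in non_sig:
            sub = table[table["index"] == index_name]
            if (sub["p_adj"] >= 0.05).all():
                non_sig[index_name] += 1
    return {
        **{f"{k}_non_significant_rate": v / n_reps for k, v in non_sig.items()},
        "n_reps": n_reps,
    }
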
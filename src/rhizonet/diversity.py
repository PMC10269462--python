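"""Alpha/beta diversity and group-comparison statistics.

Alpha diversity is summarized per sample by Shannon entropy (nats),
Pielou evenness and the bias-corrected Chao1 richness estimator. Beta
diversity uses Bray-Curtis dissimilarity with a permutation PERMANOVA
(pseudo-F on the distance-matrix sum-of-squares partition). Group
comparisons of per-sample measurements use rank tests with
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, wilcoxon
from skbio.diversity.alpha import chao1, pielou_e, shannon
from statsmodels.stats.multitest import multipletests

__all__ = [
    "alpha_diversity",
    "alpha_diversity_tests",
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "compare_groups",
    "adjust_bh",
    "compare_traits",
]


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon (nats), Pielou evenness and bias-corrected Chao1.

    Pielou evenness is Shannon divided by ``ln(observed richness)`` and is
    defined as 1.0 for a single-taxon sample. Chao1 uses the
    bias-corrected form ``S_obs + F1*(F1-1)/(2*(F2+1))`` which stays
    finite when no doubletons are observed.
    """
    rows = {}
    for sample in counts.columns:
        vec = counts[sample].to_numpy()
        if vec.sum() == 0:
            raise ValueError(f"all-zero sample {sample!r} has no diversity")
        richness = int(np.count_nonzero(vec))
        h = float(shannon(vec, base=np.e))
        pielou = 1.0 if richness == 1 else float(h / np.log(richness))
        rows[sample] = {
            "shannon": h,
            "pielou": pielou,
            "chao1": float(chao1(vec, bias_corrected=True)),
            "observed_richness": richness,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def compare_groups(
    x,
    y,
    paired: bool = False,
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Two-sided rank test between two groups of measurements.

    The default is the independent-sample rank-sum (Mann-Whitney) test:
    the study design compares unpaired treatment groups, for which a
    signed-rank test is undefined. ``paired=True`` switches to the
    Wilcoxon signed-rank test on per-pair differences. The exact null
    distribution is used when both groups have at most ``exact_max_n``
    observations; otherwise the tie-corrected normal approximation.

    Returns ``(statistic, p)``. All-tied input yields p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all observations tied; p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal group sizes")
        d = x - y
        if np.all(d == 0):
            warnings.warn("all paired differences zero; p-value set to 1", stacklevel=2)
            return 0.0, 1.0
        stat, p = wilcoxon(x, y)
        return float(stat), float(p)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if max(x.size, y.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def alpha_diversity_tests(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "treatment",
    within: str | None = "crop",
    paired: bool = False,
) -> pd.DataFrame:
    """Rank tests of each alpha index between every pair of groups.

    When ``within`` names a metadata column (e.g. crop), comparisons are
    made separately inside each of its levels. P-values are BH-adjusted
    across the whole result table.
    """
    meta = metadata.loc[alpha.index]
    blocks = [(None, meta)] if within is None else list(meta.groupby(within, sort=True))
    records = []
    indices = [c for c in alpha.columns if c != "observed_richness"]
    for block_label, block in blocks:
        groups = sorted(block[group_col].unique())
        for g1, g2 in itertools.combinations(groups, 2):
            s1 = block.index[block[group_col] == g1]
            s2 = block.index[block[group_col] == g2]
            for index_name in indices:
                stat, p = compare_groups(
                    alpha.loc[s1, index_name], alpha.loc[s2, index_name], paired=paired
                )
                records.append(
                    {
                        "block": block_label,
                        "index": index_name,
                        "group1": g1,
                        "group2": g2,
                        "statistic": stat,
                        "p": p,
                    }
                )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["p_adj"] = adjust_bh(table["p"])
    return table


def bray_curtis(rel_abund: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity matrix.

    ``BC(a, b) = 1 - 2 * sum(min(a_i, b_i)) / sum(a_i + b_i)`` — symmetric,
    zero diagonal, values in [0, 1] for nonnegative input.
    """
    if rel_abund.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    mat = squareform(pdist(rel_abund.to_numpy().T, metric="braycurtis"))
    return pd.DataFrame(mat, index=rel_abund.columns, columns=rel_abund.columns)


@dataclass(frozen=True)
class PermanovaResult:
    """Outcome of a one-way PERMANOVA on a distance matrix."""

    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int
    seed: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dist: pd.DataFrame,
    grouping,
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) with a permutation p-value.

    The total sum of squares of the distance matrix is partitioned into
    among- and within-group parts; ``pseudo-F = (SS_A/(a-1)) /
    (SS_W/(n-a))`` and ``R^2 = SS_A / SS_T``. The p-value is
    ``(1 + #{permuted F >= observed}) / (1 + permutations)`` under random
    relabeling of samples, so it is bounded below by ``1/(permutations+1)``.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(pd.Series(grouping))
    if d.shape[0] != d.shape[1] or d.shape[0] != labels.size:
        raise ValueError("distance matrix and grouping sizes disagree")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError(f"singleton group(s): {groups[counts < 2].tolist()}")
    n, a = labels.size, groups.size
    d2 = d**2
    ss_total = d2.sum() / (2.0 * n)

    def f_stat(lbl: np.ndarray) -> float:
        ss_w = _ss_within(d2, lbl, groups)
        ss_a = ss_total - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    observed = f_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if f_stat(rng.permutation(labels)) >= observed:
            hits += 1
    ss_w_obs = _ss_within(d2, labels, groups)
    return PermanovaResult(
        pseudo_f=float(observed),
        r_squared=float((ss_total - ss_w_obs) / ss_total),
        p_value=(1 + hits) / (1 + permutations),
        permutations=permutations,
        seed=seed,
    )


def compare_traits(
    metadata: pd.DataFrame,
    traits: list[str],
    group_col: str = "treatment",
    within: str | None = "crop",
) -> pd.DataFrame:
    """Rank tests of each trait between group pairs, BH-adjusted overall.

    Missing trait values are dropped pairwise (never treated as zero).
    """
    records = []
    blocks = (
        [(None, metadata)] if within is None else list(metadata.groupby(within, sort=True))
    )
    for block_label, block in blocks:
        groups = sorted(block[group_col].unique())
        for g1, g2 in itertools.combinations(groups, 2):
            for trait in traits:
                v1 = block.loc[block[group_col] == g1, trait].dropna()
                v2 = block.loc[block[group_col] == g2, trait].dropna()
                stat, p = compare_groups(v1, v2)
                records.append(
                    {
                        "block": block_label,
                        "trait": trait,
                        "group1": g1,
                        "group2": g2,
                        "statistic": stat,
                        "p": p,
                    }
                )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["p_adj"] = adjust_bh(table["p"])
    return table
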
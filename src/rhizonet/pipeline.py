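"""End-to-end orchestration: one config in, a directory of reports out.

``run_pipeline`` executes the stages in dependency order — ingest or
simulate, rarefy + relative abundance, diversity statistics, per-group
co-occurrence networks with modules and robustness curves, module-trait
correlations and hubs for the coated groups, and the focal-genus
knockout — writing every artifact as a tab-separated text file plus a
JSON run manifest that records every parameter (no silent defaults) and
a hash of the configuration. Reruns with an identical config reproduce
identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as rio
from .diversity import alpha_diversity, alpha_diversity_tests, bray_curtis, permanova
from .knockout import knockout_experiment
from .modules import all_module_eigengenes, correlate_modules, hub_nodes
from .network import (
    DEFAULT_FRACTIONS,
    NetworkParams,
    build_network,
    detect_modules,
    filter_taxa,
    negative_edge_ratio,
    robustness_curve,
    spearman_matrix,
)
from .synthetic import SyntheticScenario, generate_counts, scenario_from_yaml

log = logging.getLogger("rhizonet")

__all__ = ["RunConfig", "run_pipeline", "report_summary", "PipelineError"]

META_COLS = ("crop", "treatment", "replicate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully recorded in the manifest."""

    out_dir: str
    # input: either a synthetic scenario (inline or YAML path) or table paths
    scenario: SyntheticScenario | None = None
    scenario_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    metadata_path: str | None = None
    # normalization
    rarefy_depth: int | None = None  # None -> minimum sample total
    # grouping
    crop_col: str = "crop"
    treatment_col: str = "treatment"
    coated_label: str = "coated"
    control_label: str = "control"
    # network stage
    rho_threshold: float = 0.8
    p_threshold: float = 0.05
    p_adjust: bool = False
    min_prevalence: int = 3
    min_mean_abundance: float = 1e-4
    min_module_size: int = 5
    removal_fractions: tuple = DEFAULT_FRACTIONS
    robustness_reps: int = 50
    # diversity stage
    permutations: int = 999
    # knockout stage
    knockout_genus: str | None = "Trichoderma"
    match_threshold: float = 0.5
    # randomness
    seed: int = 0

    def network_params(self) -> NetworkParams:
        return NetworkParams(
            rho_threshold=self.rho_threshold,
            p_threshold=self.p_threshold,
            p_adjust=self.p_adjust,
            min_prevalence=self.min_prevalence,
            min_mean_abundance=self.min_mean_abundance,
        )

    def validate(self) -> None:
        self.network_params().validate()
        if not 0 < self.match_threshold <= 1:
            raise ValueError(f"match_threshold must be in (0, 1]: {self.match_threshold}")
        if self.permutations < 1 or self.robustness_reps < 1:
            raise ValueError("permutations and robustness_reps must be positive")
        fr = np.asarray(self.removal_fractions, dtype=float)
        if fr.size and (fr.min() <= 0 or fr.max() >= 1):
            raise ValueError("removal fractions must lie strictly in (0, 1)")
        has_scenario = self.scenario is not None or self.scenario_path is not None
        has_tables = self.counts_path is not None
        if has_scenario == has_tables:
            raise ValueError("config needs exactly one of scenario or table paths")
        if has_tables and (self.taxonomy_path is None or self.metadata_path is None):
            raise ValueError("table input needs counts, taxonomy and metadata paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
        d["removal_fractions"] = list(self.removal_fractions)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "removal_fractions" in data:
            data["removal_fractions"] = tuple(data["removal_fractions"])
        return cls(**data)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "rarefy", "permanova", "modules", "robustness", "knockout")
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, ss.spawn(len(names)))
    }


def _write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError(f"stage config: {exc}") from exc
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "stages": [],
        "results": {},
    }

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append(name)

    # --- input ------------------------------------------------------
    stage("input")
    try:
        if config.counts_path is not None:
            counts = rio.read_count_table(config.counts_path)
            taxonomy = rio.read_taxonomy(config.taxonomy_path)
            metadata = rio.read_metadata(config.metadata_path)
        else:
            scenario = config.scenario or scenario_from_yaml(config.scenario_path)
            scenario = dataclasses.replace(scenario, seed=seeds["simulate"])
            counts, taxonomy, metadata = generate_counts(scenario)
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc
    rio.write_count_table(counts, out / "counts.tsv")
    rio.write_taxonomy(taxonomy, out / "taxonomy.tsv")
    rio.write_metadata(metadata, out / "metadata.tsv")
    missing = metadata.index.symmetric_difference(counts.columns)
    if len(missing):
        raise PipelineError(f"stage input: samples mismatch: {missing.tolist()}")

    # --- normalize --------------------------------------------------
    stage("normalize")
    try:
        rare = rio.rarefy(counts, depth=config.rarefy_depth, seed=seeds["rarefy"])
        rel = rio.to_relative_abundance(counts)
    except Exception as exc:
        raise PipelineError(f"stage normalize: {exc}") from exc
    rio.write_count_table(rare, out / "rarefied.tsv")
    _write(rel, out / "relative_abundance.tsv")

    # --- diversity --------------------------------------------------
    stage("diversity")
    try:
        alpha = alpha_diversity(rare)
        _write(alpha, out / "alpha_diversity.tsv")
        tests = alpha_diversity_tests(
            alpha, metadata, group_col=config.treatment_col, within=config.crop_col
        )
        _write(tests, out / "alpha_tests.tsv", index=False)
        dist = bray_curtis(rel)
        _write(dist, out / "bray_curtis.tsv")
        perm_rows = []
        for crop, block in metadata.groupby(config.crop_col, sort=True):
            if block[config.treatment_col].nunique() < 2:
                continue
            res = permanova(
                dist.loc[block.index, block.index],
                block[config.treatment_col],
                permutations=config.permutations,
                seed=seeds["permanova"],
            )
            perm_rows.append(
                {
                    "crop": crop,
                    "pseudo_f": res.pseudo_f,
                    "r_squared": res.r_squared,
                    "p": res.p_value,
                    "permutations": res.permutations,
                }
            )
        _write(pd.DataFrame(perm_rows), out / "permanova.tsv", index=False)
        manifest["results"]["permanova"] = perm_rows
    except Exception as exc:
        raise PipelineError(f"stage diversity: {exc}") from exc

    # --- per-group networks ----------------------------------------
    stage("networks")
    params = config.network_params()
    groups = (
        metadata[[config.crop_col, config.treatment_col]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    networks, partitions = {}, {}
    net_rows = []
    for crop, treatment in sorted(groups):
        label = f"{crop}_{treatment}"
        samples = metadata.index[
            (metadata[config.crop_col] == crop)
            & (metadata[config.treatment_col] == treatment)
        ]
        try:
            grp_rel = filter_taxa(
                rel[list(samples)], params.min_prevalence, params.min_mean_abundance
            )
            rho, p = spearman_matrix(grp_rel)
            net = build_network(rho, p, params, group=label)
            part = detect_modules(
                net, seed=seeds["modules"], min_module_size=config.min_module_size
            )
            curve = robustness_curve(
                net,
                fractions=config.removal_fractions,
                n_reps=config.robustness_reps,
                seed=seeds["robustness"],
            )
        except Exception as exc:
            raise PipelineError(f"stage networks ({label}): {exc}") from exc
        networks[(crop, treatment)] = net
        partitions[(crop, treatment)] = part
        _write(net.edge_table(), out / f"network_{label}.edges.tsv", index=False)
        _write(
            part.assignment.rename("module").to_frame(),
            out / f"modules_{label}.tsv",
        )
        _write(curve.to_frame(), out / f"robustness_{label}.tsv", index=False)
        net_rows.append(
            {
                "group": label,
                "nodes": len(net.nodes),
                "edges": net.n_edges,
                "negative_edge_ratio": negative_edge_ratio(net)
                if net.n_edges
                else float("nan"),
                "modularity": part.modularity,
                "n_modules": len(part.module_ids),
                "natural_connectivity": curve.intact,
                "robustness_auc": curve.auc,
            }
        )
    _write(pd.DataFrame(net_rows), out / "network_summary.tsv", index=False)
    manifest["results"]["networks"] = net_rows

    # --- module-trait correlations and hubs (coated groups) --------
    stage("module_trait")
    trait_cols = [
        c
        for c in metadata.columns
        if c not in META_COLS and pd.api.types.is_numeric_dtype(metadata[c])
    ]
    knockout_targets = {}
    for (crop, treatment), net in networks.items():
        if treatment != config.coated_label:
            continue
        label = f"{crop}_{treatment}"
        part = partitions[(crop, treatment)]
        try:
            hubs = hub_nodes(net, part)
            _write(hubs, out / f"hubs_{label}.tsv")
            if part.module_ids and trait_cols:
                samples = metadata.index[
                    (metadata[config.crop_col] == crop)
                    & (metadata[config.treatment_col] == treatment)
                ]
                eigs = all_module_eigengenes(rel[list(samples)], part)
                corr = correlate_modules(
                    eigs, metadata.loc[samples, trait_cols]
                )
                _write(corr.to_long(), out / f"module_trait_{label}.tsv", index=False)
        except Exception as exc:
            raise PipelineError(f"stage module_trait ({label}): {exc}") from exc
        if config.knockout_genus:
            members = rio.genus_members(taxonomy, config.knockout_genus)
            mids = {part.module_of(m) for m in members} - {None}
            if mids:
                knockout_targets[(crop, treatment)] = part.members(min(mids))

    # --- knockout ---------------------------------------------------
    stage("knockout")
    ko_rows = []
    for (crop, treatment), target in knockout_targets.items():
        label = f"{crop}_{treatment}"
        samples = metadata.index[
            (metadata[config.crop_col] == crop)
            & (metadata[config.treatment_col] == treatment)
        ]
        try:
            results = knockout_experiment(
                counts,
                taxonomy,
                metadata,
                config.knockout_genus,
                samples=samples,
                params=params,
                seed=seeds["knockout"],
                min_module_size=config.min_module_size,
                match_threshold=config.match_threshold,
                coated_label=config.coated_label,
                control_label=config.control_label,
                treatment_col=config.treatment_col,
                target_module=target,
            )
        except Exception as exc:
            raise PipelineError(f"stage knockout ({label}): {exc}") from exc
        for mode, res in results.items():
            ko_rows.append(
                {
                    "group": label,
                    "genus": res.genus,
                    "mode": mode,
                    "target_size": len(target),
                    "best_module": res.match.best_module,
                    "shared_proportion": res.match.shared_proportion,
                    "jaccard": res.match.jaccard,
                    "persists": res.persists,
                }
            )
    _write(pd.DataFrame(ko_rows), out / "knockout.tsv", index=False)
    manifest["results"]["knockout"] = ko_rows

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def report_summary(run_dir) -> str:
    """One-page text summary of a completed run directory."""
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"no manifest in {run}: run not completed")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"rhizonet run {manifest['config_hash']} (v{manifest['version']})",
        "=" * 48,
    ]

    def section(title, filename, fmt):
        lines.append("")
        lines.append(title)
        path = run / filename
        if not path.exists():
            lines.append("  stage not run")
            return
        df = pd.read_csv(path, sep="\t")
        lines.extend(fmt(df))

    section(
        "Per-group networks",
        "network_summary.tsv",
        lambda df: [
            f"  {r.group}: {r.nodes} nodes, {r.edges} edges, "
            f"negative-edge ratio {r.negative_edge_ratio:.3f}, "
            f"nat. connectivity {r.natural_connectivity:.3f} "
            f"(robustness AUC {r.robustness_auc:.3f})"
            for r in df.itertuples()
        ],
    )
    section(
        "PERMANOVA (Bray-Curtis, treatment within crop)",
        "permanova.tsv",
        lambda df: [
            f"  {r.crop}: pseudo-F {r.pseudo_f:.2f}, R2 {r.r_squared:.3f}, "
            f"p {r.p:.3g} ({r.permutations} permutations)"
            for r in df.itertuples()
        ],
    )
    section(
        "Alpha-diversity group tests",
        "alpha_tests.tsv",
        lambda df: [
            f"  {r.block} {r.metric} {r.group1} vs {r.group2}: "
            f"p {r.p:.3f} (adj {r.p_adj:.3f})"
            for r in df.rename(columns={"index": "metric"}).itertuples()
        ],
    )

    def top_corr(df):
        df = df.dropna(subset=["r"])
        df = df.reindex(df["r"].abs().sort_values(ascending=False).index)
        return [
            f"  module {int(r.module)} ~ {r.variable}: r {r.r:+.2f} (p {r.p:.3g})"
            for r in df.head(5).itertuples()
        ]

    for path in sorted(run.glob("module_trait_*.tsv")):
        section(f"Top module-trait correlations [{path.stem}]", path.name, top_corr)
    section(
        "Knockout",
        "knockout.tsv",
        lambda df: [
            f"  {r.group} {r.mode} {r.genus}: shared proportion "
            f"{r.shared_proportion:.2f} -> "
            f"{'persists' if r.persists else 'dissolved'}"
            for r in df.itertuples()
        ]
        if len(df)
        else ["  no knockout target (focal genus in no labeled module)"],
    )
    return "\n".join(lines)
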
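"""Synthetic rhizosphere OTU tables with planted network structure.

The generator emulates a seed-coating pot experiment: a factorial design
of crops x (coated, control) groups, a focal inoculant genus enriched
only under coating, planted correlated modules nucleated by latent
factors, antagonistic (negatively coupled) taxon pairs concentrated in
coated groups, and plant/enzyme traits linearly coupled to a module's
latent activity.

Counts follow a log-normal--multinomial law: per-taxon baseline
log-abundances are normal across taxa, latent module factors and
idiosyncratic noise act additively on the log scale, the per-sample
log-abundance vector is closed to a composition, and reads are drawn
multinomially at an overdispersed sequencing depth. Everything is
reproducible from one scenario seed via seed-sequence stream splitting
(one child stream per draw component).

A note on the focal ("keystone") module geometry: satellites of a
module are conditionally independent given the latent factor, so two
satellites that each correlate with the focal taxon at rho can never
correlate with each other much below rho^2. A star-shaped module whose
spokes pass a strict |rho| > 0.8 edge rule therefore keeps satellite-
satellite correlations near 0.64-0.8: a *large* keystone module would
survive removal of its hub. The default focal module is consequently
compact — the focal taxon plus four satellites, exactly the minimum
module size — so that hub removal leaves too few correlated members to
constitute a module, which is the regime where an in-silico knockout
can dissolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio

__all__ = [
    "ModuleSpec",
    "TraitSpec",
    "SyntheticScenario",
    "ScenarioError",
    "generate_counts",
    "generate_fixture_suite",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

DEFAULT_GROUPS = (
    ("maize", "coated"),
    ("maize", "control"),
    ("watermelon", "coated"),
    ("watermelon", "control"),
)


class ScenarioError(ValueError):
    """The scenario configuration is internally inconsistent."""


@dataclass(frozen=True)
class ModuleSpec:
    """A planted correlated module.

    ``loading`` (in [0, 1]) scales how strongly members follow the
    module's per-sample latent factor. A ``focal`` module is nucleated by
    the inoculant taxon: its factor is active only in coated groups, the
    focal taxon itself follows the factor with loading 1 and reduced
    idiosyncratic noise (the inoculant's abundance *is* the colonization
    readout), and the remaining members are satellites.
    """

    n_members: int
    loading: float
    focal: bool = False


@dataclass(frozen=True)
class TraitSpec:
    """A trait/enzyme variable linearly coupled to one module's factor."""

    name: str
    module: int  # index into SyntheticScenario.module_spec
    coupling: float  # slope on the latent factor; negative for disease
    noise_sd: float
    base: float = 0.0


def _default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec(n_members=5, loading=0.95, focal=True),
        ModuleSpec(n_members=8, loading=0.85),
    )


def _default_traits() -> tuple[TraitSpec, ...]:
    # couplings sized for generating correlation ~0.75 with the factor
    return (
        TraitSpec("root_length_cm", 0, 3.0, 2.6, base=30.0),
        TraitSpec("stem_diameter_mm", 0, 0.8, 0.7, base=10.0),
        TraitSpec("root_dry_weight_g", 0, 1.0, 0.9, base=5.0),
        TraitSpec("disease_incidence_pct", 0, -8.0, 7.0, base=40.0),
        TraitSpec("urease", 0, 2.5, 2.2, base=20.0),
        TraitSpec("acid_phosphatase", 0, 2.0, 1.7, base=15.0),
        TraitSpec("cellulase", 0, 2.0, 1.5, base=12.0),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic experiment.

    Defaults mirror the emulated study design: four crop x treatment
    groups of six replicates (24 samples), ~200 fungal OTUs, a compact
    focal module nucleated by the inoculant genus, one ordinary
    background module, antagonistic pairs added under coating, and
    traits coupled to the focal module.
    """

    n_taxa: int = 200
    n_samples_per_group: int = 6
    groups: tuple = DEFAULT_GROUPS
    module_spec: tuple = field(default_factory=_default_modules)
    focal_genus_label: str = "Trichoderma"
    coated_label: str = "coated"
    competition_strength: float = 1.0
    n_positive_pairs: int = 15
    n_baseline_negative_pairs: int = 3
    pair_loading: float = 0.95
    focal_enrichment: float = 5.0
    focal_noise_factor: float = 0.2
    focal_baseline: float = 0.0
    focal_self_loading: float = 0.75
    member_baseline_boost: float = 1.0
    member_baseline_sigma: float = 0.5
    baseline_sigma: float = 1.5
    factor_scale: float = 1.5
    noise_sigma: float = 0.35
    sequencing_depth_mean: float = 20000.0
    overdispersion: float = 0.3
    trait_spec: tuple = field(default_factory=_default_traits)
    seed: int = 0

    # -- derived ------------------------------------------------------
    @property
    def n_competition_pairs(self) -> int:
        return int(round(self.competition_strength * 10))

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(self.groups)

    def validate(self) -> None:
        if self.n_taxa < 2 or self.n_samples_per_group < 1:
            raise ScenarioError("need at least 2 taxa and 1 sample per group")
        if not self.groups or len(set(self.groups)) != len(self.groups):
            raise ScenarioError("groups must be nonempty and unique")
        if sum(m.n_members for m in self.module_spec) > self.n_taxa:
            raise ScenarioError("module member counts exceed n_taxa")
        for m in self.module_spec:
            if not 0 <= m.loading <= 1:
                raise ScenarioError(f"loading outside [0, 1]: {m.loading}")
            if m.n_members < 2:
                raise ScenarioError("a module needs at least 2 members")
        if not 0 <= self.pair_loading <= 1:
            raise ScenarioError(f"pair_loading outside [0, 1]: {self.pair_loading}")
        if self.competition_strength < 0:
            raise ScenarioError("competition_strength must be >= 0")
        if self.sequencing_depth_mean <= 0:
            raise ScenarioError("sequencing depth must be positive")
        if self.overdispersion <= 0:
            raise ScenarioError("overdispersion must be positive")
        n_pair_taxa = 2 * (
            self.n_positive_pairs
            + self.n_baseline_negative_pairs
            + self.n_competition_pairs
        )
        if sum(m.n_members for m in self.module_spec) + n_pair_taxa > self.n_taxa:
            raise ScenarioError("modules plus coupled pairs exceed n_taxa")
        for t in self.trait_spec:
            if not 0 <= t.module < len(self.module_spec):
                raise ScenarioError(
                    f"trait {t.name!r} references missing module {t.module}"
                )
            if t.noise_sd < 0:
                raise ScenarioError(f"trait {t.name!r} has negative noise sd")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SyntheticScenario":
        """A no-structure scenario: no modules, pairs, enrichment or traits."""
        defaults = dict(
            module_spec=(),
            trait_spec=(),
            competition_strength=0.0,
            n_positive_pairs=0,
            n_baseline_negative_pairs=0,
            focal_enrichment=1.0,
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _taxon_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OTU_{i + 1:0{width}d}" for i in range(n)]


def generate_counts(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one (count table, taxonomy, sample metadata) triple.

    Returns taxa x samples integer counts, a six-rank taxonomy (the
    focal module's first member carries the focal genus label) and
    per-sample metadata with crop/treatment/replicate plus trait values.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    (s_base, s_member, s_factor, s_noise, s_depth, s_count, s_trait) = [
        np.random.default_rng(c) for c in ss.spawn(7)
    ]

    taxa = _taxon_ids(scenario.n_taxa)
    n_taxa, n_samples = scenario.n_taxa, scenario.n_samples
    sample_ids, crop_col, treat_col, rep_col = [], [], [], []
    for crop, treatment in scenario.groups:
        for r in range(1, scenario.n_samples_per_group + 1):
            sample_ids.append(f"{crop}_{treatment}_{r}")
            crop_col.append(crop)
            treat_col.append(treatment)
            rep_col.append(r)
    coated = np.array([t == scenario.coated_label for t in treat_col])

    # --- membership draws (modules, then coupled pairs, all disjoint)
    order = s_member.permutation(n_taxa)
    cursor = 0
    module_members: list[list[int]] = []
    for spec in scenario.module_spec:
        module_members.append(list(order[cursor : cursor + spec.n_members]))
        cursor += spec.n_members

    def take_pairs(k: int) -> list[tuple[int, int]]:
        nonlocal cursor
        out = []
        for _ in range(k):
            out.append((int(order[cursor]), int(order[cursor + 1])))
            cursor += 2
        return out

    positive_pairs = take_pairs(scenario.n_positive_pairs)
    baseline_neg_pairs = take_pairs(scenario.n_baseline_negative_pairs)
    competition_pairs = take_pairs(scenario.n_competition_pairs)

    focal_taxon: int | None = None
    for spec, members in zip(scenario.module_spec, module_members):
        if spec.focal:
            focal_taxon = members[0]
            break

    # --- log-abundance assembly
    log_x = np.tile(
        s_base.normal(0.0, scenario.baseline_sigma, size=n_taxa)[:, None],
        (1, n_samples),
    )
    pair_taxa = [
        t
        for pair in positive_pairs + baseline_neg_pairs + competition_pairs
        for t in pair
    ]
    member_all = [t for members in module_members for t in members] + pair_taxa
    # module members and coupled-pair taxa get their own, narrower baseline
    # law: planted structure lives in the moderately-abundant range where
    # rank correlations are informative (neither drowned by count noise nor
    # compositionally dominant)
    if member_all:
        log_x[member_all, :] = s_base.normal(
            scenario.member_baseline_boost,
            scenario.member_baseline_sigma,
            size=len(member_all),
        )[:, None]
    if focal_taxon is not None:
        # the inoculant's baseline is pinned (not drawn from the log-normal
        # tail) so it cannot compositionally dominate the community
        log_x[focal_taxon, :] = scenario.focal_baseline

    # Factors that are active only under coating must not change any
    # taxon's marginal abundance law between groups (coating rewires the
    # dependence structure, not the margins): where a shared factor is
    # inactive, each member receives an independent draw of the same
    # magnitude instead of nothing.
    module_factors = np.zeros((len(scenario.module_spec), n_samples))
    for mi, (spec, members) in enumerate(zip(scenario.module_spec, module_members)):
        active = coated if spec.focal else np.ones(n_samples, dtype=bool)
        z = s_factor.normal(size=n_samples)
        module_factors[mi] = np.where(active, z, 0.0)
        for t in members:
            if spec.focal and t == focal_taxon:
                loading = scenario.focal_self_loading
            else:
                loading = spec.loading
            a = loading * scenario.factor_scale
            indep = s_factor.normal(size=n_samples)
            log_x[t, :] += a * np.where(active, z, indep)

    def add_pair(pair, signs, active):
        w = s_factor.normal(size=n_samples)
        a = scenario.pair_loading * scenario.factor_scale
        for t, sgn in zip(pair, signs):
            indep = s_factor.normal(size=n_samples)
            log_x[t, :] += a * np.where(active, sgn * w, indep)

    always = np.ones(n_samples, dtype=bool)
    for pair in positive_pairs:
        add_pair(pair, (+1, +1), always)
    for pair in baseline_neg_pairs:
        add_pair(pair, (+1, -1), always)
    for pair in competition_pairs:
        add_pair(pair, (+1, -1), coated)

    noise = s_noise.normal(0.0, scenario.noise_sigma, size=(n_taxa, n_samples))
    if focal_taxon is not None:
        noise[focal_taxon, :] *= scenario.focal_noise_factor
    log_x += noise

    if focal_taxon is not None and scenario.focal_enrichment != 1.0:
        log_x[focal_taxon, coated] += np.log(scenario.focal_enrichment)

    # --- closure and multinomial sampling at overdispersed depth
    log_x -= log_x.max(axis=0, keepdims=True)
    comp = np.exp(log_x)
    comp /= comp.sum(axis=0, keepdims=True)
    shape = 1.0 / scenario.overdispersion**2
    depths = np.maximum(
        1,
        np.rint(
            s_depth.gamma(shape, scenario.sequencing_depth_mean / shape, size=n_samples)
        ).astype(int),
    )
    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = s_count.multinomial(depths[j], comp[:, j])

    count_table = pd.DataFrame(counts, index=pd.Index(taxa, name=rio.TAXON_INDEX),
                               columns=pd.Index(sample_ids, name=rio.SAMPLE_INDEX))

    # --- taxonomy: generic fungal ranks, one genus per OTU
    tax = pd.DataFrame(
        {
            "kingdom": "Fungi",
            "phylum": "Ascomycota",
            "class": "Sordariomycetes",
            "order": "Hypocreales",
            "family": "Hypocreaceae",
            "genus": [f"Genus_{i + 1:04d}" for i in range(n_taxa)],
        },
        index=pd.Index(taxa, name=rio.TAXON_INDEX),
    )
    if focal_taxon is not None:
        tax.iloc[focal_taxon, tax.columns.get_loc("genus")] = (
            scenario.focal_genus_label
        )

    # --- metadata with factor-coupled traits
    meta = pd.DataFrame(
        {"crop": crop_col, "treatment": treat_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name=rio.SAMPLE_INDEX),
    )
    for t in scenario.trait_spec:
        z = module_factors[t.module]
        meta[t.name] = t.base + t.coupling * z + s_trait.normal(0.0, t.noise_sd,
                                                                size=n_samples)
    return count_table, tax, meta


def planted_truth(scenario: SyntheticScenario) -> dict:
    """Ground-truth memberships for a scenario (same stream-splitting rule).

    Returns taxon-id lists per planted module plus the coupled pair
    lists, for checking recovery against the generator.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    s_member = np.random.default_rng(ss.spawn(7)[1])
    taxa = np.array(_taxon_ids(scenario.n_taxa))
    order = s_member.permutation(scenario.n_taxa)
    cursor = 0
    modules = []
    focal_taxon = None
    for spec in scenario.module_spec:
        members = taxa[order[cursor : cursor + spec.n_members]].tolist()
        cursor += spec.n_members
        if spec.focal and focal_taxon is None:
            focal_taxon = members[0]
        modules.append({"members": members, "focal": spec.focal,
                        "loading": spec.loading})

    def take_pairs(k):
        nonlocal cursor
        out = []
        for _ in range(k):
            out.append((taxa[order[cursor]], taxa[order[cursor + 1]]))
            cursor += 2
        return out

    return {
        "modules": modules,
        "focal_taxon": focal_taxon,
        "positive_pairs": take_pairs(scenario.n_positive_pairs),
        "baseline_negative_pairs": take_pairs(scenario.n_baseline_negative_pairs),
        "competition_pairs": take_pairs(scenario.n_competition_pairs),
    }


# ---------------------------------------------------------------------------
# Plain-text scenario configs and fixture suite


def scenario_to_yaml(scenario: SyntheticScenario, path) -> None:
    data = asdict(scenario)
    data["groups"] = [list(g) for g in scenario.groups]
    data["module_spec"] = [asdict(m) for m in scenario.module_spec]
    data["trait_spec"] = [asdict(t) for t in scenario.trait_spec]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def scenario_from_yaml(path) -> SyntheticScenario:
    data = yaml.safe_load(Path(path).read_text())
    data["groups"] = tuple(tuple(g) for g in data.get("groups", DEFAULT_GROUPS))
    data["module_spec"] = tuple(
        ModuleSpec(**m) for m in data.get("module_spec", [])
    )
    data["trait_spec"] = tuple(TraitSpec(**t) for t in data.get("trait_spec", []))
    return SyntheticScenario(**data)


def generate_fixture_suite(out_dir, seed: int = 0) -> list[Path]:
    """Write a small deterministic set of scenario configs and tables.

    The suite contains one null scenario (no planted structure) and one
    planted-module scenario, each with its scenario YAML, count table,
    taxonomy and metadata. Repeated calls with the same seed reproduce
    identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = {
        "null": SyntheticScenario.null(seed=seed, n_taxa=80),
        "planted": SyntheticScenario(
            n_taxa=80,
            module_spec=(
                ModuleSpec(n_members=5, loading=0.95, focal=True),
                ModuleSpec(n_members=6, loading=0.85),
            ),
            n_positive_pairs=5,
            n_baseline_negative_pairs=2,
            seed=seed + 1,
        ),
    }
    paths = []
    for name, scenario in scenarios.items():
        counts, tax, meta = generate_counts(scenario)
        base = out / name
        scenario_to_yaml(scenario, base.with_suffix(".scenario.yaml"))
        rio.write_count_table(counts, base.with_suffix(".counts.tsv"))
        rio.write_taxonomy(tax, base.with_suffix(".taxonomy.tsv"))
        rio.write_metadata(meta, base.with_suffix(".metadata.tsv"))
        paths += [
            base.with_suffix(".scenario.yaml"),
            base.with_suffix(".counts.tsv"),
            base.with_suffix(".taxonomy.tsv"),
            base.with_suffix(".metadata.tsv"),
        ]
    return paths
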
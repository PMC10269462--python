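import dataclasses
import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from rhizonet import io as rio
from rhizonet.network import spearman_matrix
from rhizonet.synthetic import (
    ModuleSpec,
    ScenarioError,
    SyntheticScenario,
    TraitSpec,
    generate_counts,
    generate_fixture_suite,
    planted_truth,
    scenario_from_yaml,
    scenario_to_yaml,
)


class TestScenarioValidation:
    def test_default_scenario_is_valid(self):
        SyntheticScenario().validate()

    @pytest.mark.parametrize(
        "overrides",
        [
            {"module_spec": (ModuleSpec(5, 1.2),)},
            {"module_spec": (ModuleSpec(300, 0.9),)},
            {"sequencing_depth_mean": 0},
            {"overdispersion": 0},
            {"trait_spec": (TraitSpec("t", 5, 1.0, 1.0),)},
            {"groups": ()},
            {"competition_strength": -1},
        ],
    )
    def test_inconsistent_scenarios_rejected(self, overrides):
        with pytest.raises(ScenarioError):
            dataclasses.replace(SyntheticScenario(), **overrides).validate()

    def test_yaml_round_trip(self, tmp_path):
        scenario = SyntheticScenario(seed=9, n_taxa=50)
        path = tmp_path / "scenario.yaml"
        scenario_to_yaml(scenario, path)
        assert scenario_from_yaml(path) == scenario


class TestGenerateCounts:
    def test_shape_and_sign_contract(self):
        scenario = SyntheticScenario(seed=1)
        counts, tax, meta = generate_counts(scenario)
        assert counts.shape == (200, 24)
        assert (counts.to_numpy() >= 0).all()
        assert counts.dtypes.eq(np.int64).all()
        assert list(tax.index) == list(counts.index)
        assert list(meta.index) == list(counts.columns)

    def test_reproducible_from_seed(self):
        a, _, ma = generate_counts(SyntheticScenario(seed=5))
        b, _, mb = generate_counts(SyntheticScenario(seed=5))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ma, mb)
        c, _, _ = generate_counts(SyntheticScenario(seed=6))
        assert not a.equals(c)

    def test_depths_near_configured_mean(self):
        counts, _, _ = generate_counts(SyntheticScenario(seed=2))
        totals = counts.sum(axis=0)
        assert 0.4 * 20000 < totals.min()
        assert totals.max() < 2.5 * 20000

    def test_focal_genus_label_assigned_once(self):
        scenario = SyntheticScenario(seed=3)
        _, tax, _ = generate_counts(scenario)
        assert (tax["genus"] == "Trichoderma").sum() == 1
        assert planted_truth(scenario)["focal_taxon"] == (
            tax.index[tax["genus"] == "Trichoderma"][0]
        )

    def test_traits_present_with_disease_negative_coupling(self):
        scenario = SyntheticScenario(seed=4)
        _, _, meta = generate_counts(scenario)
        assert "disease_incidence_pct" in meta.columns
        assert {"crop", "treatment", "replicate"} <= set(meta.columns)


def _member_nonmember_rho(scenario):
    counts, _, meta = generate_counts(scenario)
    coated = meta.index[meta["treatment"] == "coated"]
    rel = rio.to_relative_abundance(counts[list(coated)])
    members = planted_truth(scenario)["modules"][0]["members"]
    rho, _ = spearman_matrix(rel)
    pairs = list(itertools.combinations(members, 2))
    member_mean = np.nanmean([rho.loc[a, b] for a, b in pairs])
    others = [t for t in rel.index if t not in members][: len(members)]
    other_pairs = list(itertools.combinations(others, 2))
    other_mean = np.nanmean([rho.loc[a, b] for a, b in other_pairs])
    return member_mean, other_mean


class TestPlantedStructure:
    def test_zero_loading_module_is_null(self):
        diffs = []
        for seed in range(8):
            scenario = SyntheticScenario(
                n_taxa=60,
                n_samples_per_group=15,
                groups=(("maize", "coated"),),
                module_spec=(ModuleSpec(8, 0.0),),
                n_positive_pairs=0,
                n_baseline_negative_pairs=0,
                competition_strength=0.0,
                trait_spec=(),
                seed=seed,
            )
            m, o = _member_nonmember_rho(scenario)
            diffs.append(m - o)
        # member pairs behave like background pairs when the loading is 0
        assert abs(np.mean(diffs)) < 0.1

    def test_planted_members_strongly_correlated(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            scenario = SyntheticScenario(
                n_taxa=200,
                n_samples_per_group=30,
                groups=(("maize", "coated"),),
                module_spec=(ModuleSpec(15, 0.9),),
                n_positive_pairs=0,
                n_baseline_negative_pairs=0,
                competition_strength=0.0,
                trait_spec=(),
                seed=100 + seed,
            )
            member_mean, _ = _member_nonmember_rho(scenario)
            if member_mean > 0.8:
                hits += 1
        assert hits >= 0.9 * reps

    def test_enrichment_monotonically_raises_focal_abundance(self):
        means = []
        for factor in (1.0, 3.0, 9.0):
            scenario = SyntheticScenario(seed=42, focal_enrichment=factor)
            counts, _, meta = generate_counts(scenario)
            rel = rio.to_relative_abundance(counts)
            coated = meta.index[meta["treatment"] == "coated"]
            focal = planted_truth(scenario)["focal_taxon"]
            means.append(rel.loc[focal, coated].mean())
        assert means[0] < means[1] < means[2]

    def test_no_competition_means_sign_symmetric_null_edges(self):
        # without planted negative couplings, significant negative
        # correlations among unstructured taxa are no more common than
        # significant positive ones
        neg, pos = 0, 0
        for seed in range(5):
            scenario = SyntheticScenario.null(
                seed=seed, n_taxa=80, n_samples_per_group=10,
                groups=(("maize", "coated"), ("maize", "control")),
            )
            counts, _, meta = generate_counts(scenario)
            coated = meta.index[meta["treatment"] == "coated"]
            rel = rio.to_relative_abundance(counts[list(coated)])
            rho, p = spearman_matrix(rel)
            iu = np.triu_indices(len(rho), k=1)
            sig = (p.to_numpy()[iu] < 0.05) & (np.abs(rho.to_numpy()[iu]) > 0.8)
            signs = np.sign(rho.to_numpy()[iu][sig])
            neg += int((signs < 0).sum())
            pos += int((signs > 0).sum())
        total = neg + pos
        if total >= 20:
            assert abs(neg - pos) < 0.5 * total


class TestFixtureSuite:
    def test_deterministic_bytes(self, tmp_path):
        a = generate_fixture_suite(tmp_path / "a", seed=7)
        b = generate_fixture_suite(tmp_path / "b", seed=7)
        for pa, pb in zip(a, b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_seed_changes_content(self, tmp_path):
        a = generate_fixture_suite(tmp_path / "a", seed=7)
        c = generate_fixture_suite(tmp_path / "c", seed=8)
        counts_a = next(p for p in a if p.name.endswith("counts.tsv"))
        counts_c = next(p for p in c if p.name.endswith("counts.tsv"))
        assert counts_a.read_bytes() != counts_c.read_bytes()

    def test_contains_null_and_planted_scenarios(self, tmp_path):
        paths = generate_fixture_suite(tmp_path, seed=1)
        names = {p.name for p in paths}
        assert "null.scenario.yaml" in names
        assert "planted.scenario.yaml" in names
        planted = scenario_from_yaml(tmp_path / "planted.scenario.yaml")
        assert any(m.focal for m in planted.module_spec)
        null = scenario_from_yaml(tmp_path / "null.scenario.yaml")
        assert null.module_spec == ()
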
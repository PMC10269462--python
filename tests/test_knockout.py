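import warnings

import numpy as np
import pandas as pd
import pytest

from rhizonet import io as rio
from rhizonet import knockout as ko
from rhizonet.network import ModulePartition
from rhizonet.synthetic import (
    ModuleSpec,
    SyntheticScenario,
    generate_counts,
    planted_truth,
)


def make_taxonomy(genera):
    return pd.DataFrame(
        {r: "" for r in rio.RANKS} | {"genus": list(genera.values())},
        index=pd.Index(list(genera), name="taxon_id"),
    )


class TestRemove:
    def test_drops_member_rows_only(self, small_tables):
        _, counts, tax, _ = small_tables
        members = rio.genus_members(tax, "Trichoderma")
        out = ko.knockout_remove(counts, tax, "Trichoderma")
        assert set(counts.index) - set(out.index) == set(members)
        pd.testing.assert_frame_equal(out, counts.drop(index=members))

    def test_idempotent(self, small_tables):
        _, counts, tax, _ = small_tables
        once = ko.knockout_remove(counts, tax, "Trichoderma")
        with pytest.warns(UserWarning, match="no-op"):
            twice = ko.knockout_remove(once, tax, "Trichoderma")
        pd.testing.assert_frame_equal(once, twice)

    def test_absent_genus_warns(self, small_tables):
        _, counts, tax, _ = small_tables
        with pytest.warns(UserWarning, match="no-op"):
            out = ko.knockout_remove(counts, tax, "Nosuchgenus")
        pd.testing.assert_frame_equal(out, counts)


class TestReduce:
    def _setup(self, coated_counts, control_counts):
        taxa = [f"t{i}" for i in range(len(coated_counts))]
        counts = pd.DataFrame(
            np.column_stack([coated_counts, coated_counts, control_counts,
                             control_counts]),
            index=pd.Index(taxa, name="taxon_id"),
            columns=["co1", "co2", "ct1", "ct2"],
        )
        genera = {t: ("Trichoderma" if i == 0 else f"G{i}")
                  for i, t in enumerate(taxa)}
        tax = make_taxonomy(genera)
        meta = pd.DataFrame(
            {"treatment": ["coated", "coated", "control", "control"]},
            index=counts.columns,
        )
        return counts, tax, meta

    def test_scaled_mean_matches_control(self):
        counts, tax, meta = self._setup([400, 4800, 4800], [100, 4950, 4950])
        out = ko.knockout_reduce(counts, tax, "Trichoderma", meta)
        rel = out / out.sum(axis=0)
        coated_mean = rel.loc["t0", ["co1", "co2"]].mean()
        control_mean = rel.loc["t0", ["ct1", "ct2"]].mean()
        assert coated_mean == pytest.approx(control_mean, abs=2e-3)
        # factor near the naive abundance ratio 0.25
        assert out.loc["t0", "co1"] / 400 == pytest.approx(0.25, abs=0.05)

    def test_control_samples_untouched(self):
        counts, tax, meta = self._setup([400, 4800, 4800], [100, 4950, 4950])
        out = ko.knockout_reduce(counts, tax, "Trichoderma", meta)
        pd.testing.assert_frame_equal(out[["ct1", "ct2"]], counts[["ct1", "ct2"]])
        pd.testing.assert_frame_equal(
            out.drop(index="t0"), counts.drop(index="t0")
        )

    def test_equal_means_leave_table_unchanged(self):
        counts, tax, meta = self._setup([100, 900, 900], [100, 900, 900])
        out = ko.knockout_reduce(counts, tax, "Trichoderma", meta)
        pd.testing.assert_frame_equal(out, counts)

    def test_genus_absent_from_control_zeroes_coated(self):
        counts, tax, meta = self._setup([100, 900, 900], [0, 950, 950])
        with pytest.warns(UserWarning, match="absent from control"):
            out = ko.knockout_reduce(counts, tax, "Trichoderma", meta)
        assert (out.loc["t0", ["co1", "co2"]] == 0).all()


class TestMatchModules:
    def _partition(self, mapping):
        nodes = sorted({n for ns in mapping.values() for n in ns})
        assignment = pd.Series(np.nan, index=pd.Index(nodes, name="taxon_id"))
        for mid, ns in mapping.items():
            assignment.loc[list(ns)] = mid
        return ModulePartition(assignment, 0.5, 0, 5)

    def test_partial_overlap(self):
        part = self._partition({1: ["B", "C", "D", "E"]})
        match = ko.match_modules(["A", "B", "C", "D"], part)
        assert match.best_module == 1
        assert match.shared_proportion == pytest.approx(0.75)
        assert match.jaccard == pytest.approx(3 / 5)

    def test_disjoint_and_identical(self):
        part = self._partition({1: ["X", "Y", "Z"]})
        assert ko.match_modules(["A", "B"], part).shared_proportion == 0.0
        part2 = self._partition({1: ["A", "B"]})
        assert ko.match_modules(["A", "B"], part2).shared_proportion == 1.0

    def test_tie_break_prefers_smaller_id(self):
        part = self._partition({1: ["A", "X"], 2: ["B", "Y"]})
        match = ko.match_modules(["A", "B"], part)
        assert match.best_module == 1

    def test_restriction_to_surviving_nodes(self):
        part = self._partition({1: ["B", "C"]})
        match = ko.match_modules(
            ["A", "B", "C"], part, rebuilt_network_nodes=["B", "C"]
        )
        assert match.shared_proportion == pytest.approx(1.0)

    def test_merging_modules_never_lowers_proportion(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            nodes = [f"n{i}" for i in range(12)]
            labels = rng.integers(1, 4, size=12)
            split = self._partition(
                {m: [n for n, l in zip(nodes, labels) if l == m] for m in (1, 2, 3)}
            )
            merged = self._partition(
                {1: [n for n, l in zip(nodes, labels) if l in (1, 2)],
                 3: [n for n, l in zip(nodes, labels) if l == 3]}
            )
            target = list(rng.choice(nodes, size=5, replace=False))
            assert (
                ko.match_modules(target, merged).shared_proportion
                >= ko.match_modules(target, split).shared_proportion - 1e-12
            )

    def test_empty_target_rejected(self):
        part = self._partition({1: ["A"]})
        with pytest.raises(ValueError):
            ko.match_modules([], part)


class TestKnockoutExperiment:
    @pytest.fixture(scope="class")
    def structured(self):
        scenario = SyntheticScenario(
            n_taxa=100,
            n_samples_per_group=30,
            groups=(("maize", "coated"), ("maize", "control")),
            module_spec=(
                ModuleSpec(n_members=5, loading=0.95, focal=True),
                ModuleSpec(n_members=8, loading=0.9),
            ),
            n_positive_pairs=6,
            n_baseline_negative_pairs=2,
            competition_strength=0.0,
            trait_spec=(),
            seed=21,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts, tax, meta = generate_counts(scenario)
        return scenario, counts, tax, meta

    def test_focal_removal_dissolves_module(self, structured):
        _, counts, tax, meta = structured
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = ko.knockout_experiment(
                counts, tax, meta, "Trichoderma", modes=("remove",), seed=0
            )
        res = results["remove"]
        assert res.match.shared_proportion < 0.5
        assert not res.persists

    def test_unrelated_genus_removal_keeps_module(self, structured):
        scenario, counts, tax, meta = structured
        truth = planted_truth(scenario)
        structured_taxa = {
            t for m in truth["modules"] for t in m["members"]
        } | {t for pair in truth["positive_pairs"] for t in pair}
        bystander = next(t for t in counts.index if t not in structured_taxa)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res_focal = ko.knockout_experiment(
                counts, tax, meta, "Trichoderma", modes=("remove",), seed=0
            )
            results = ko.knockout_experiment(
                counts, tax, meta, tax.loc[bystander, "genus"],
                modes=("remove",), seed=0,
                target_module=res_focal["remove"].target_module,
            )
        # removing an unstructured bystander leaves the focal module intact
        assert results["remove"].match.shared_proportion >= 0.5
        assert results["remove"].persists

    def test_untouched_independent_module_fully_persists(self, structured):
        scenario, counts, tax, meta = structured
        truth = planted_truth(scenario)
        background = [m for m in truth["modules"] if not m["focal"]][0]["members"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = ko.knockout_experiment(
                counts, tax, meta, "Trichoderma",
                modes=("remove",), seed=0, target_module=background,
            )
        assert results["remove"].match.shared_proportion == pytest.approx(1.0)

    def test_unknown_genus_rejected(self, structured):
        _, counts, tax, meta = structured
        with pytest.raises(ValueError):
            ko.knockout_experiment(counts, tax, meta, "Nosuchgenus")
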
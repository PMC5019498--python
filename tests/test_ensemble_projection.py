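"""Sampling design, registry arithmetic, weighted ensembles, projection, consensus."""

import numpy as np
import pandas as pd
import pytest

from landrefugia import ensemble_projection as ep
from landrefugia import synthetic_world as sw
from landrefugia.climatic_partition import LeafPartition
from landrefugia.sdm_methods import PredictionSurface, binarize


def make_cells(n):
    return pd.DataFrame({"cell_id": np.arange(n)})


class TestMakeDesign:
    def test_sample_and_split_arithmetic_with_round_rule(self):
        design = ep.make_design(make_cells(1000), seed=0)
        assert len(design.modeling_ids) == 250
        assert len(design.holdout_ids) == 750
        for calib, valid in design.replicates:
            assert len(calib) == 188  # round(0.75 * 250)
            assert len(valid) == 62
            assert np.intersect1d(calib, valid).size == 0
            assert set(np.r_[calib, valid]) == set(design.modeling_ids)
        assert design.n_replicates == 10

    def test_fixed_seed_reproduces_the_design(self):
        a = ep.make_design(make_cells(400), seed=42)
        b = ep.make_design(make_cells(400), seed=42)
        assert np.array_equal(a.modeling_ids, b.modeling_ids)
        for (c1, v1), (c2, v2) in zip(a.replicates, b.replicates):
            assert np.array_equal(c1, c2) and np.array_equal(v1, v2)
        c = ep.make_design(make_cells(400), seed=43)
        assert not np.array_equal(a.modeling_ids, c.modeling_ids)

    def test_full_sample_fraction_uses_every_cell(self):
        design = ep.make_design(make_cells(100), sample_frac=1.0, seed=0)
        assert len(design.modeling_ids) == 100
        assert len(design.holdout_ids) == 0

    @pytest.mark.parametrize("frac", [0.0, 1.5, -0.1])
    def test_invalid_fractions_rejected(self, frac):
        with pytest.raises(ValueError):
            ep.make_design(make_cells(100), sample_frac=frac)


class TestRegistry:
    def test_replicating_the_published_design_counts(self):
        """12 method slots x 10 replicates x 38 leaves across three GCMs
        enumerate 4560 fit jobs collapsing to 456 averaged surfaces."""
        slots = [f"m{i}" for i in range(12)]
        leaves = {
            "gcm_a": list(range(1, 14)),  # 13
            "gcm_b": list(range(1, 14)),  # 13
            "gcm_c": list(range(1, 13)),  # 12
        }
        registry = ep.enumerate_jobs(slots, leaves, n_replicates=10)
        assert len(registry) == 4560
        averaged = registry.drop_duplicates(["gcm", "method", "leaf"])
        assert len(averaged) == 456

    def test_general_m_r_l_arithmetic(self):
        registry = ep.enumerate_jobs(["a", "b"], {"g": [1, 2, 3]}, n_replicates=4)
        assert len(registry) == 2 * 4 * 3
        assert registry.duplicated().sum() == 0


class TestTssWeightedEnsemble:
    def mk(self, suit):
        return PredictionSurface(
            cell_ids=np.arange(len(suit)), suitability=np.asarray(suit, float)
        )

    def test_equal_weights_give_arithmetic_mean(self):
        out = ep.tss_weighted_ensemble([self.mk([0.2, 0.6]), self.mk([0.4, 1.0])], [0.5, 0.5])
        np.testing.assert_allclose(out.suitability, [0.3, 0.8])

    def test_documented_weighted_example(self):
        out = ep.tss_weighted_ensemble([self.mk([1.0]), self.mk([0.5])], [0.8, 0.4])
        assert out.suitability[0] == pytest.approx((0.8 * 1.0 + 0.4 * 0.5) / 1.2)
        assert out.suitability[0] == pytest.approx(0.8333333333)

    def test_zero_weight_member_fully_excluded(self):
        out = ep.tss_weighted_ensemble([self.mk([0.9, 0.1]), self.mk([0.0, 1.0])], [0.7, 0.0])
        np.testing.assert_allclose(out.suitability, [0.9, 0.1])

    def test_negative_weights_clamp_to_zero(self):
        out = ep.tss_weighted_ensemble([self.mk([0.9]), self.mk([0.1])], [0.5, -0.3])
        assert out.suitability[0] == pytest.approx(0.9)

    def test_all_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            ep.tss_weighted_ensemble([self.mk([0.5])], [-0.1])

    def test_output_bounded_by_member_min_max_everywhere(self):
        rng = np.random.default_rng(0)
        members = [self.mk(rng.uniform(0, 1, 50)) for _ in range(4)]
        weights = rng.uniform(0, 1, 4)
        out = ep.tss_weighted_ensemble(members, list(weights))
        stack = np.stack([m.suitability for m in members])
        assert (out.suitability >= stack.min(axis=0) - 1e-12).all()
        assert (out.suitability <= stack.max(axis=0) + 1e-12).all()


class TestFitAllAndProject:
    def test_projection_on_baseline_reproduces_current_surfaces(
        self, default_world, statistical_run
    ):
        _, _, _, baseline, _, _ = default_world
        run = statistical_run
        proj = ep.project(run, baseline)
        for key, current in run.surfaces.items():
            future = proj[key]
            np.testing.assert_allclose(future.suitability, current.suitability, atol=1e-9)
            assert future.threshold == current.threshold

    def test_gcm_mismatch_between_fit_and_stack_rejected(
        self, default_world, statistical_run
    ):
        domain, _, scenarios, _, _, _ = default_world
        wrong = sw.generate_climate(domain, scenarios["gcm_b"]["rcp45"], seed=1)
        with pytest.raises(ValueError, match="GCM mismatch"):
            ep.project(statistical_run, wrong)

    def test_fit_registry_covers_methods_leaves_replicates(self, statistical_run):
        run = statistical_run
        expected = {
            (m, leaf, r)
            for m in ("glm", "gam", "mars")
            for leaf in run.leaf_ids
            for r in range(run.design.n_replicates)
        }
        assert set(run.fits) == expected
        # one averaged surface per (slot, leaf): 3 methods + 1 family
        assert len(run.surfaces) == 4 * len(run.leaf_ids)

    def test_internal_tss_high_on_separable_world(self, statistical_run):
        tss = statistical_run.internal_tss
        assert len(tss) == 3 * len(statistical_run.leaf_ids) * 10
        # single replicates can dip (few validation presences); the bulk is high
        assert tss["tss"].mean() > 0.85
        assert tss["tss"].min() > 0.2

    def test_warm_adapted_leaf_grows_monotonically_under_warming(self):
        """With a monotone (linear-logit) model, a leaf bounded only from
        below in temperature cannot lose cells when every cell warms."""
        domain = sw.DomainSpec(-10.0, 0.0, -60.0, -50.0)
        rules = sw.RuleSet(
            rules=(sw.Rule("hot", (("bio1", ">=", 26.0),)),),
            default_category="cool",
        )
        base = sw.generate_climate(domain, sw.ScenarioSpec("g", "baseline"), seed=0)
        lc = sw.generate_landcover(base, rules)
        cells = sw.apply_anthropogenic(lc, base, hotspots=None, seed=0)
        assignments = pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "leaf_id": np.where(cells["landcover"] == "hot", 1, 2),
                "predicted_category": cells["landcover"],
                "landcover": cells["landcover"],
            }
        )
        partition = LeafPartition(
            assignments=assignments,
            leaf_category={1: "hot", 2: "cool"},
            leaf_counts={1: int((assignments["leaf_id"] == 1).sum()), 2: 0},
            leaf_composition={1: {}, 2: {}},
            misclassified_share={},
        )
        design = ep.make_design(cells, seed=0)
        run = ep.fit_all(
            cells,
            partition,
            design,
            variables=["bio1"],
            methods=["glm"],
            families={},
            hyperparams={"glm": {"quadratic": False}},
            seed=0,
            gcm_id="g",
        )
        area = {"baseline": int(run.surfaces[("glm", 1)].binary.sum())}
        for shift in (0.5, 1.0, 2.0):
            fut = sw.generate_climate(
                domain, sw.ScenarioSpec("g", "rcp45", shifts={"bio1": shift}), seed=0
            )
            proj = ep.project(run, fut)
            area[shift] = int(proj[("glm", 1)].binary.sum())
        assert area["baseline"] <= area[0.5] <= area[1.0] <= area[2.0]

    def test_leaf_with_too_few_presences_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        n = 200
        cells = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "bio1": rng.uniform(0, 1, n),
                "landcover": "a",
            }
        )
        leaf_id = np.ones(n, int)
        leaf_id[:6] = 2  # tiny leaf: ~1-2 cells reach any calibration split
        assignments = pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "leaf_id": leaf_id,
                "predicted_category": "a",
                "landcover": "a",
            }
        )
        partition = LeafPartition(
            assignments=assignments,
            leaf_category={1: "a", 2: "a"},
            leaf_counts={1: n - 6, 2: 6},
            leaf_composition={1: {}, 2: {}},
            misclassified_share={},
        )
        design = ep.make_design(cells, seed=0)
        with caplog.at_level("WARNING"):
            run = ep.fit_all(
                cells, partition, design, variables=["bio1"],
                methods=["glm"], families={}, seed=0,
            )
        assert 2 in run.skipped_leaves
        assert "skipped" in caplog.text


class TestAggregateAndConsensus:
    def part(self, leaf_category):
        return LeafPartition(
            assignments=pd.DataFrame(
                {"cell_id": [], "leaf_id": [], "predicted_category": [], "landcover": []}
            ),
            leaf_category=leaf_category,
            leaf_counts={},
            leaf_composition={},
            misclassified_share={},
        )

    def test_one_leaf_per_category_is_identity(self):
        a = np.array([True, False, True])
        out = ep.aggregate_leaves({1: a}, self.part({1: "forest"}))
        np.testing.assert_array_equal(out["forest"], a)

    def test_disjoint_leaves_sum_overlapping_leaves_union(self):
        a = np.array([True, False, False, False])
        b = np.array([False, True, False, False])
        c = np.array([True, True, False, False])
        part = self.part({1: "f", 2: "f", 3: "f"})
        assert ep.aggregate_leaves({1: a, 2: b}, part)["f"].sum() == 2
        assert ep.aggregate_leaves({1: a, 3: c}, part)["f"].sum() == 2  # union < sum

    def test_unmapped_leaf_rejected(self):
        with pytest.raises(ValueError, match="without a category"):
            ep.aggregate_leaves({9: np.array([True])}, self.part({1: "f"}))

    def test_unanimous_agreement_returns_any_member(self):
        m = np.array([[True, False], [False, True]])
        out = ep.gcm_consensus({"g1": {"f": m}, "g2": {"f": m.copy()}})
        np.testing.assert_array_equal(out["f"], m)

    def test_single_dissenting_gcm_removes_the_cell(self):
        a = np.array([True, True])
        b = np.array([True, False])
        out = ep.gcm_consensus({"g1": {"f": a}, "g2": {"f": b}})
        np.testing.assert_array_equal(out["f"], [True, False])

    def test_consensus_subset_of_every_member_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            members = {
                f"g{i}": {"f": rng.random((6, 6)) < 0.6} for i in range(3)
            }
            out = ep.gcm_consensus(members)["f"]
            for m in members.values():
                assert not (out & ~m["f"]).any()

    def test_majority_rule_behind_flag(self):
        maps = {
            "g1": {"f": np.array([True, True, False])},
            "g2": {"f": np.array([True, False, False])},
            "g3": {"f": np.array([True, True, False])},
        }
        out = ep.gcm_consensus(maps, rule="majority")
        np.testing.assert_array_equal(out["f"], [True, True, False])

    def test_missing_category_for_one_gcm_rejected(self):
        with pytest.raises(ValueError, match="lacks categories"):
            ep.gcm_consensus({"g1": {"f": np.array([True])}, "g2": {}})

    def test_fewer_than_two_gcms_rejected(self):
        with pytest.raises(ValueError):
            ep.gcm_consensus({"g1": {"f": np.array([True])}})
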
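"""Shared fixtures: small synthetic worlds and one full pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from landrefugia import climatic_partition as cp
from landrefugia import ensemble_projection as ep
from landrefugia import synthetic_world as sw
from landrefugia.config import load_config
from landrefugia.pipeline import run_all


@pytest.fixture(scope="session")
def small_domain() -> sw.DomainSpec:
    """20x20 cells of 0.5 degrees — enough structure, fast to model."""
    return sw.DomainSpec(lat_min=-10.0, lat_max=0.0, lon_min=-60.0, lon_max=-50.0)


@pytest.fixture(scope="session")
def two_category_rules() -> sw.RuleSet:
    """Forest where warm, shrub elsewhere: one latitudinal boundary."""
    return sw.RuleSet(
        rules=(sw.Rule("forest", (("bio1", ">=", 25.0),)),),
        default_category="shrub",
    )


@pytest.fixture(scope="session")
def small_world(small_domain, two_category_rules):
    """Noiseless baseline stack + landcover + cell table on the small domain."""
    scenario = sw.ScenarioSpec(gcm_id="test", rcp_id="baseline")
    stack = sw.generate_climate(small_domain, scenario, noise_sd=0.0, seed=7)
    landcover = sw.generate_landcover(stack, two_category_rules)
    cells = sw.apply_anthropogenic(landcover, stack, hotspots=None, seed=7)
    return stack, landcover, cells


@pytest.fixture(scope="session")
def default_world():
    """The default 40x40 five-category world with default noise."""
    domain = sw.default_domain()
    rules = sw.default_rules()
    scenarios = sw.default_scenarios()
    baseline = sw.generate_climate(domain, scenarios["gcm_a"]["baseline"], seed=1)
    landcover = sw.generate_landcover(baseline, rules)
    cells = sw.apply_anthropogenic(landcover, baseline, hotspots=None, seed=1)
    return domain, rules, scenarios, baseline, landcover, cells


@pytest.fixture(scope="session")
def default_partition(default_world):
    """CV-pruned tree + leaf partition on the default world (one GCM)."""
    _, _, _, _, _, cells = default_world
    control = cp.TreeControl(cv_reps=20)
    model = cp.fit_tree(cells, list(sw.BIOCLIM_VARIABLES), control, gcm_id="gcm_a")
    pruned = cp.prune_by_cv(model, cells, seed=0)
    partition = cp.assign_leaves(pruned, cells)
    return pruned, partition


@pytest.fixture(scope="session")
def statistical_run(default_world, default_partition):
    """Fitted statistical-family models on the default world (one GCM)."""
    _, _, _, _, _, cells = default_world
    model, partition = default_partition
    design = ep.make_design(cells, seed=1)
    run = ep.fit_all(
        cells,
        partition,
        design,
        variables=model.selected_variables(),
        methods=["glm", "gam", "mars"],
        seed=1,
        gcm_id="gcm_a",
    )
    return run


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run: default world, statistical family, fixed seed.

    Used by the acceptance tests; runs once per session (a few minutes).
    """
    cfg = load_config(
        {
            "modeling": {"methods": ["glm", "gam", "mars"]},
            "seed": 1,
        }
    )
    return run_all(cfg)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
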
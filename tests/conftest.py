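import numpy as np
import pytest

import tilecode as tc


@pytest.fixture(scope="session")
def constructs12():
    return tc.random_constructs(12, seed=101)


@pytest.fixture(scope="session")
def negatives3():
    return tc.random_constructs(3, seed=102, prefix="NEG")


@pytest.fixture(scope="session")
def layout12(constructs12, negatives3):
    return tc.build_array_layout(constructs12, negatives3)


@pytest.fixture(scope="session")
def dilution_noiseless():
    """50-construct engineered dilution pools in the exact linear regime."""
    cons = tc.random_constructs(50, seed=3)
    negs = tc.random_constructs(5, seed=4, prefix="NEG")
    layout = tc.build_array_layout(cons, negs)
    pool_spec = tc.PoolSpec.dilution_series([c.construct_id for c in cons], per_subpool=5)
    table, affinities = tc.simulate_dilution_experiment(
        layout, pool_spec,
        affinity_sigma=1.0, overlap_rho=0.6,
        noise_cv=0.0, background_level=0.0,
        abundance_scale=1e9, seed=7,
    )
    return {"layout": layout, "pool_spec": pool_spec, "table": table,
            "affinities": affinities}


@pytest.fixture(scope="session")
def dilution_noisy():
    """100-construct dilution pools with 20% multiplicative noise."""
    cons = tc.random_constructs(100, seed=31)
    negs = tc.random_constructs(11, seed=32, prefix="NEG")
    layout = tc.build_array_layout(cons, negs)
    pool_spec = tc.PoolSpec.dilution_series([c.construct_id for c in cons], per_subpool=10)
    table, _ = tc.simulate_dilution_experiment(layout, pool_spec, noise_cv=0.2, seed=33)
    quant = tc.quantify_dilution(table, layout, pool_spec, k_fold=4)
    return {"layout": layout, "pool_spec": pool_spec, "table": table, "quant": quant}


@pytest.fixture(scope="session")
def screen_sim():
    """100-construct screen, 10 constructs depleted 4-fold, triplicates."""
    cons = tc.random_constructs(100, seed=11)
    negs = tc.random_constructs(11, seed=12, prefix="NEG")
    layout = tc.build_array_layout(cons, negs)
    ids = [c.construct_id for c in cons]
    depleted = ids[:10]
    scenario = tc.ScreenScenario(
        depleted_ids=frozenset(depleted),
        log2_effect={c: -2.0 for c in depleted},
        seed=5,
    )
    table, truth = tc.simulate_negative_selection(layout, scenario)
    agg, bg = tc.quantify_screen(table, layout, k_fold=10)
    results = tc.screen_results(agg)
    return {"layout": layout, "scenario": scenario, "table": table,
            "truth": truth, "agg": agg, "background": bg,
            "results": results, "depleted": set(depleted)}


@pytest.fixture(scope="session")
def saturating_screen():
    """300-construct screen with heterogeneous effects and saturation on.

    Under saturation, per-probe affinity no longer cancels from the
    t_end/t_zero ratio, so overlap-correlated affinities leave an
    overlap-correlated fingerprint on position-wise log2 ratios.
    """
    rng = np.random.default_rng(21)
    cons = tc.random_constructs(300, seed=21)
    negs = tc.random_constructs(11, seed=22, prefix="NEG")
    layout = tc.build_array_layout(cons, negs, n_subarrays=1)
    ids = [c.construct_id for c in cons]
    effects = dict(zip(ids, np.round(rng.normal(-1.0, 0.7, len(ids)), 3)))
    scenario = tc.ScreenScenario(
        depleted_ids=frozenset(ids),
        log2_effect=effects,
        affinity_sigma=1.0, overlap_rho=0.8, noise_cv=0.1,
        saturation_smax=2000.0, seed=23,
    )
    table, truth = tc.simulate_negative_selection(layout, scenario)
    agg, _ = tc.quantify_screen(table, layout, k_fold=10)
    return {"layout": layout, "table": table, "agg": agg}
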
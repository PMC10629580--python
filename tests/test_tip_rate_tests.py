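import numpy as np
import pandas as pd
import pytest

import chronodiv as cd
from chronodiv.errors import DataError
from chronodiv.tip_rate_tests import BMSimulator, TipTable

from .oracles import path_walk_es


def test_es_cherry_with_stem_counts_both_edges():
    tree = cd.parse_newick("((A:1,B:1):1);")
    es = cd.es_statistic(tree)
    assert es.loc["A", "ES"] == pytest.approx(1.5)
    assert es.loc["A", "DR"] == pytest.approx(2.0 / 3.0)
    assert es.loc["B", "ES"] == es.loc["A", "ES"]


def test_es_symmetric_tree_uniform(balanced_tree):
    es = cd.es_statistic(balanced_tree)
    assert es["ES"].nunique() == 1
    assert (es["ES"] > 0).all()


def test_es_matches_path_walk_oracle(yule_tree_50):
    es = cd.es_statistic(yule_tree_50)
    oracle = path_walk_es(yule_tree_50)
    for label, val in oracle.items():
        assert es.loc[label, "ES"] == pytest.approx(val, abs=1e-12)


def test_essim_detects_its_own_statistic(yule_tree_50):
    """Trait equal to log(DR) is maximally associated with itself."""
    log_dr = np.log(cd.es_statistic(yule_tree_50)["DR"].to_numpy())
    rep = cd.essim_test(yule_tree_50, log_dr, n_sim=200, seed=0)
    assert rep.p_value <= 2.0 / 201.0


def test_essim_deterministic_and_validates(yule_tree_50):
    trait = cd.simulate_traits(yule_tree_50, "bm", seed=12)
    a = cd.essim_test(yule_tree_50, trait, n_sim=150, seed=7)
    b = cd.essim_test(yule_tree_50, trait, n_sim=150, seed=7)
    assert a.p_value == b.p_value and a.statistic == b.statistic
    with pytest.raises(DataError):
        cd.essim_test(yule_tree_50, np.ones(yule_tree_50.n_tips), n_sim=150)


def _tip_table(rates, regimes, trait, name="trait"):
    return TipTable(
        pd.DataFrame(
            {"tip_rate": rates, "regime": regimes, name: trait},
            index=[f"t{i}" for i in range(len(rates))],
        )
    )


def test_strapp_single_regime_p_is_one():
    tips = _tip_table([1.0] * 10, [0] * 10, np.arange(10.0))
    rep = cd.strapp_test(tips, "trait", stat="spearman", n_perm=199, seed=0)
    assert rep.p_value == 1.0


def test_strapp_power_with_separated_regimes():
    """Trait equal to the regime mean rate across 10 well-separated
    regimes is detected at p <= 0.01 in >= 90% of replicates."""
    rng = np.random.default_rng(0)
    hits = 0
    n_rep = 20
    for rep_i in range(n_rep):
        regimes = np.repeat(np.arange(10), 8)
        regime_rates = np.geomspace(0.05, 2.0, 10)
        rates = regime_rates[regimes]
        trait = rates + rng.normal(0, 1e-3, size=rates.size)
        tips = _tip_table(rates, regimes, trait)
        rep = cd.strapp_test(tips, "trait", stat="spearman", n_perm=999, seed=rep_i)
        hits += rep.p_value <= 0.01
    assert hits >= int(0.9 * n_rep)


@pytest.mark.parametrize("stat", ["mann_whitney", "kruskal_wallis"])
def test_strapp_rank_statistics_run(stat):
    rng = np.random.default_rng(4)
    regimes = np.repeat(np.arange(6), 10)
    rates = np.geomspace(0.1, 1.0, 6)[regimes]
    if stat == "mann_whitney":
        trait = (rng.random(60) < 0.5).astype(int)
    else:
        trait = rng.integers(0, 4, size=60)
    tips = _tip_table(rates, regimes, trait)
    rep = cd.strapp_test(tips, "trait", stat=stat, n_perm=299, seed=1)
    assert 0.0 < rep.p_value <= 1.0


def test_d_statistic_validates_and_references(yule_tree_50):
    with pytest.raises(DataError):
        cd.d_statistic(yule_tree_50, np.zeros(yule_tree_50.n_tips), 100, 100)
    trait = cd.simulate_traits(yule_tree_50, "threshold_binary", seed=3, prevalence=0.4)
    rep = cd.d_statistic(yule_tree_50, trait, n_perm=150, n_sim=150, seed=5)
    assert rep.extras["mean_d_random"] > rep.extras["mean_d_bm"]
    assert np.isfinite(rep.statistic)


def test_classify_tropical_rules():
    occ = pd.DataFrame(
        {
            "species": ["a"] * 4 + ["b"] * 4 + ["c"] * 2,
            "lat": [0.0, 10.0, -20.0, 40.0] + [30.0, 40.0, 10.0, -5.0] + [23.5, 60.0],
            "lon": 0.0,
        }
    )
    flags, _ = cd.classify_tropical(occ, mode="latitude")
    assert flags["a"] == 1  # 3 of 4 inside the band
    assert flags["b"] == 0  # exactly 50% is nontropical
    assert flags["c"] == 0  # boundary counts as inside, but only 1 of 2

    occ["mean_temp_c"] = [19.0] * 4 + [10.0] * 4 + [18.0] * 2
    flags, dropped = cd.classify_tropical(occ, mode="temperature")
    assert flags["a"] == 1  # all localities exceed 18 C
    assert flags["b"] == 0
    assert flags["c"] == 0  # exactly 18 C does not exceed 18 C
    assert dropped == []


def test_bm_simulator_variance_scales_with_depth(balanced_tree):
    sim = BMSimulator(balanced_tree)
    draws = sim.simulate(1.0, np.random.default_rng(0), n=4000)
    # every tip has root-to-tip depth 3 on the balanced tree
    assert np.allclose(draws.var(axis=0), 3.0, rtol=0.15)
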
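import numpy as np
import pytest

import chronodiv as cd
from chronodiv.errors import ConfigError
from chronodiv.synthetic_data import simulate_bd_forward


def test_climate_linear_trend_without_oscillation():
    scn = cd.ClimateScenario(
        start=1.0, end=5.0, oscillation_amplitude=0.0, noise_sd=0.0,
        step=1.0, span=30.0,
    )
    s = cd.simulate_climate(scn, seed=0)
    assert s.values[0] == pytest.approx(5.0)  # present
    assert s.values[-1] == pytest.approx(1.0)  # oldest
    assert np.interp(15.0, s.ages, s.values) == pytest.approx(3.0)
    assert np.allclose(np.diff(s.values, 2), 0.0, atol=1e-12)


def test_climate_seed_reproducibility():
    scn = cd.ClimateScenario()
    a = cd.simulate_climate(scn, seed=5)
    b = cd.simulate_climate(scn, seed=5)
    c = cd.simulate_climate(scn, seed=6)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_climate_oscillation_autocorrelation_peak():
    scn = cd.ClimateScenario(
        start=5.0, end=0.0, oscillation_amplitude=0.5, oscillation_period=5.0,
        noise_sd=0.0, step=0.5, span=60.0,
    )
    s = cd.simulate_climate(scn, seed=0)
    resid = s.values - np.polyval(np.polyfit(s.ages, s.values, 1), s.ages)

    def ac(k):
        return np.corrcoef(resid[:-k], resid[k:])[0, 1]

    # period 5 My at 0.5 My steps: strong positive autocorrelation at one
    # full period (lag 10), strong negative at the half period (lag 5)
    assert ac(10) > 0.9
    assert ac(5) < -0.9


def test_tree_seed_reproducibility_and_truth():
    cfg = cd.SimConfig(
        cd.RateSpec("constant", 0.15), None, crown_age=25.0,
        sampling_fraction=0.8, min_tips=10, max_tips=200,
    )
    t1, truth1 = cd.simulate_bd_tree(cfg, seed=3)
    t2, _ = cd.simulate_bd_tree(cfg, seed=3)
    assert t1.write_newick() == t2.write_newick()
    assert truth1["lambda"][0] == pytest.approx(0.15)
    assert t1.crown_age == pytest.approx(25.0, rel=1e-9)


def test_pure_birth_mean_tip_count():
    """Branching-process expectation: E[N] = 2 exp(lambda T)."""
    cfg = cd.SimConfig(
        cd.RateSpec("constant", 0.1), None, crown_age=20.0,
        sampling_fraction=1.0,
    )
    rng = np.random.default_rng(0)
    counts = np.array(
        [simulate_bd_forward(cfg, rng).n_sampled for _ in range(500)]
    )
    expected = 2.0 * np.exp(0.1 * 20.0)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3.0 * se


def test_sampling_fraction_halves_tip_count():
    cfg_full = cd.SimConfig(
        cd.RateSpec("constant", 0.12), None, crown_age=20.0, sampling_fraction=1.0
    )
    cfg_half = cd.SimConfig(
        cd.RateSpec("constant", 0.12), None, crown_age=20.0, sampling_fraction=0.5
    )
    full, half = [], []
    for i in range(400):
        full.append(simulate_bd_forward(cfg_full, np.random.default_rng(i)).n_sampled)
        half.append(simulate_bd_forward(cfg_half, np.random.default_rng(i)).n_sampled)
    ratio = np.mean(half) / np.mean(full)
    assert abs(ratio - 0.5) < 0.05


def test_rtt_ensemble_noise_and_mean_convergence():
    ages = np.linspace(0, 10, 21)
    truth = 0.1 + 0.02 * ages
    ens0 = cd.simulate_rtt_ensemble(ages, truth, n_samples=10, noise_sd=0.0, seed=1)
    assert np.allclose(ens0.rates, truth)
    noise_sd = 0.2
    ens = cd.simulate_rtt_ensemble(ages, truth, 2000, noise_sd, seed=1)
    rel_dev = np.abs(ens.rates.mean(axis=0) - truth) / truth
    assert rel_dev.max() < 3.0 * noise_sd / np.sqrt(2000)
    again = cd.simulate_rtt_ensemble(ages, truth, 2000, noise_sd, seed=1)
    assert np.array_equal(ens.rates, again.rates)


def test_bm_trait_variance_tracks_depth(yule_tree_50):
    draws = np.array(
        [cd.simulate_traits(yule_tree_50, "bm", seed=s) for s in range(400)]
    )
    depth = yule_tree_50.crown_age
    assert np.allclose(draws.var(axis=0).mean(), depth, rtol=0.15)


def test_threshold_binary_prevalence(yule_tree_50):
    trait = cd.simulate_traits(yule_tree_50, "threshold_binary", seed=2, prevalence=0.3)
    n1 = trait.sum()
    assert abs(n1 - 0.3 * yule_tree_50.n_tips) <= 1  # quantile thresholding
    with pytest.raises(ConfigError):
        cd.simulate_traits(yule_tree_50, "threshold_binary", prevalence=1.0)


def test_regime_rates_single_regime(yule_tree_50):
    rates, labels = cd.simulate_traits(yule_tree_50, "regime_rates", seed=0, n_regimes=1)
    assert np.unique(rates).size == 1
    assert np.unique(labels).size == 1
    rates, labels = cd.simulate_traits(yule_tree_50, "regime_rates", seed=0, n_regimes=5)
    assert np.unique(labels).size >= 2
    # every regime carries a single rate value
    for g in np.unique(labels):
        assert np.unique(rates[labels == g]).size == 1


def test_occurrence_counts_and_spread():
    region_of = {f"s{i}": "Africa" for i in range(5)}
    occ = cd.simulate_occurrences(region_of, n_per_species=10, seed=1)
    assert len(occ) == 50
    tight = cd.simulate_occurrences(region_of, spread_deg=0.0, n_per_species=3, seed=1)
    assert tight["lon"].nunique() == 1 and tight["lat"].nunique() == 1


def test_occurrences_classify_back_to_generating_region():
    """At 2 degrees of scatter, the majority region of the generated points
    recovers the generating region for nearly every species."""
    from chronodiv.synthetic_data import REGION_CENTERS

    names = list(REGION_CENTERS)
    rng = np.random.default_rng(7)
    region_of = {f"s{i}": names[int(rng.integers(len(names)))] for i in range(100)}
    occ = cd.simulate_occurrences(region_of, spread_deg=2.0, n_per_species=10, seed=7)
    centers = {r: np.array(c) for r, c in REGION_CENTERS.items()}
    correct = 0
    for sp, group in occ.groupby("species"):
        pts = group[["lon", "lat"]].to_numpy()
        dists = {r: np.linalg.norm(pts - c, axis=1).mean() for r, c in centers.items()}
        correct += min(dists, key=dists.get) == region_of[sp]
    assert correct >= 95
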
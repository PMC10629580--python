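import math

import numpy as np
import pytest

import chronodiv as cd
from chronodiv.bd_models import aicc_value, candidate_models, fit_rate_temperature_curve
from chronodiv.errors import ConfigError, DataError

from .oracles import nee_constant_rate_loglik


def test_rate_at_closed_forms(cooling_climate):
    assert cd.rate_at(cd.RateSpec("constant", 0.2), 7.0) == pytest.approx(0.2)
    assert cd.rate_at(cd.RateSpec("exp_time", 0.1, 0.05), 10.0) == pytest.approx(
        0.1 * math.exp(0.5)
    )
    flat = cd.PaleoSeries([0.0, 50.0], [2.0, 2.0])
    assert cd.rate_at(cd.RateSpec("exp_env", 0.1, -0.3, flat), 10.0) == pytest.approx(
        0.1 * math.exp(-0.6)
    )


def test_ratespec_requires_covariate_exactly_for_env():
    with pytest.raises(ConfigError):
        cd.RateSpec("exp_env", 0.1, -0.1)
    with pytest.raises(ConfigError):
        cd.RateSpec("exp_time", 0.1, -0.1, cd.PaleoSeries([0, 1], [0, 1]))


def test_likelihood_nesting_zero_slopes(yule_tree_50, cooling_climate):
    """exp models at zero slope coincide with the constant-rate model."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        lam = rng.uniform(0.05, 0.5)
        mu = lam * rng.uniform(0.0, 0.8)
        ext = cd.RateSpec("constant", mu)
        base = cd.bd_log_likelihood(
            yule_tree_50, cd.BDModel(cd.RateSpec("constant", lam), ext)
        )
        lt = cd.bd_log_likelihood(
            yule_tree_50, cd.BDModel(cd.RateSpec("exp_time", lam, 0.0), ext)
        )
        le = cd.bd_log_likelihood(
            yule_tree_50,
            cd.BDModel(cd.RateSpec("exp_env", lam, 0.0, cooling_climate), ext),
        )
        assert lt == pytest.approx(base, abs=1e-8)
        assert le == pytest.approx(base, abs=1e-8)


def test_constant_rate_likelihood_matches_nee_closed_form():
    rng = np.random.default_rng(11)
    for seed in range(8):
        lam = rng.uniform(0.05, 0.5)
        mu = lam * rng.uniform(0.0, 0.8)
        f = rng.uniform(0.3, 1.0)
        crown = math.log(25.0 / f) / (lam - mu)
        cfg = cd.SimConfig(
            cd.RateSpec("constant", lam),
            cd.RateSpec("constant", mu) if mu > 0 else None,
            crown_age=crown, sampling_fraction=f, min_tips=15, max_tips=300,
        )
        tree, _ = cd.simulate_bd_tree(cfg, seed=seed)
        model = cd.BDModel(
            cd.RateSpec("constant", lam),
            cd.RateSpec("constant", mu) if mu > 0 else None,
        )
        assert cd.bd_log_likelihood(tree, model) == pytest.approx(
            nee_constant_rate_loglik(tree, lam, mu), abs=1e-6
        )


def test_grid_refinement_stability(yule_tree_50, cooling_climate):
    """Doubling the quadrature grid changes logL far below fit tolerance."""
    model = cd.BDModel(
        cd.RateSpec("exp_env", 0.12, -0.2, cooling_climate),
        cd.RateSpec("constant", 0.03),
    )
    a = cd.bd_log_likelihood(yule_tree_50, model, grid_size=2000)
    b = cd.bd_log_likelihood(yule_tree_50, model, grid_size=4000)
    assert abs(a - b) < 1e-4


def test_degenerate_parameters_raise(yule_tree_50):
    with pytest.raises(cd.NumericalError):
        cd.bd_log_likelihood(
            yule_tree_50, cd.BDModel(cd.RateSpec("exp_time", 5.0, 9.0), None)
        )


def test_yule_mle_matches_closed_form(yule_tree_50):
    """Pure-birth analytic MLE: (n-1)/L unconditioned; conditioning on the
    crown removes one speciation factor, giving (n-2)/L."""
    L = yule_tree_50.total_branch_length()
    n = yule_tree_50.n_tips
    fit = cd.fit_model(
        yule_tree_50, cd.BDModel(cd.RateSpec("constant", 0.1), None, "none")
    )
    assert fit.estimates["lambda0"] == pytest.approx((n - 1) / L, rel=1e-4)
    fit_crown = cd.fit_model(
        yule_tree_50, cd.BDModel(cd.RateSpec("constant", 0.1), None)
    )
    assert fit_crown.estimates["lambda0"] == pytest.approx((n - 2) / L, rel=1e-4)
    assert fit_crown.converged
    assert fit_crown.k == 1


def test_fit_is_deterministic(yule_tree_50, cooling_climate):
    model = cd.BDModel(cd.RateSpec("exp_env", 0.1, -0.1, cooling_climate), None)
    a = cd.fit_model(yule_tree_50, model, seed=3)
    b = cd.fit_model(yule_tree_50, model, seed=3)
    assert a.estimates == b.estimates
    assert a.logL == b.logL


def test_aicc_worked_example_and_weights():
    assert aicc_value(-100.0, 2, 50) == pytest.approx(204.2553, abs=1e-4)
    with pytest.raises(DataError):
        aicc_value(-10.0, 5, 6)

    class Stub:
        def __init__(self, aicc):
            self.aicc, self.n = aicc, 50

    delta, w = cd.aicc_weights([Stub(100.0), Stub(100.0)])
    assert np.allclose(w, [0.5, 0.5])
    delta, w = cd.aicc_weights([Stub(100.0), Stub(102.0)])
    assert w[0] == pytest.approx(1 / (1 + math.exp(-1.0)), abs=1e-4)
    assert w[1] == pytest.approx(0.2689, abs=1e-3)
    assert delta.min() == 0.0
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_evidence_ratio_algebra():
    class Stub:
        def __init__(self, aicc):
            self.aicc, self.n = aicc, 100

    # identical AICc across all six -> perfectly symmetric support
    fits = [Stub(50.0)] * 6
    assert cd.evidence_ratio(fits[:3], fits[3:]) == pytest.approx(1.0)
    # joint weights {0.5,0.2,0.1} vs {0.1,0.05,0.05} -> 0.8/0.2 = 4
    targets = [0.5, 0.2, 0.1, 0.1, 0.05, 0.05]
    aiccs = [-2.0 * math.log(t) for t in targets]
    assert cd.evidence_ratio(
        [Stub(a) for a in aiccs[:3]], [Stub(a) for a in aiccs[3:]]
    ) == pytest.approx(4.0)


def test_candidate_set_parameter_counts(cooling_climate):
    temp, time = candidate_models(cooling_climate)
    assert [m.k for m in temp] == [2, 3, 4]
    assert [m.k for m in time] == [2, 3, 4]
    assert all(m.speciation.form == "exp_env" for m in temp)
    assert all(m.speciation.form == "exp_time" for m in time)


def test_rate_temperature_curve_exact_recovery(cooling_climate):
    ages = np.linspace(0.0, 9.5, 25)
    T = cd.interpolate_series(cd.tukey_smooth(cooling_climate), ages)
    rates = 0.3 * np.exp(-0.8 * T)
    out = fit_rate_temperature_curve(ages, rates, cooling_climate, window=10.0)
    assert out["a"] == pytest.approx(0.3, abs=1e-8)
    assert out["b"] == pytest.approx(-0.8, abs=1e-8)
    assert out["r2"] == pytest.approx(1.0)

    flat = fit_rate_temperature_curve(
        ages, np.full_like(ages, 0.2), cooling_climate, window=10.0
    )
    assert flat["b"] == pytest.approx(0.0, abs=1e-10)

    with pytest.raises(DataError):
        fit_rate_temperature_curve(ages[:2], rates[:2], cooling_climate, window=10.0)


def test_rate_temperature_curve_noise_robust(cooling_climate):
    """Slope recovered within 10% under 1% additive noise (median of 100)."""
    ages = np.linspace(0.0, 10.0, 40)
    T = cd.interpolate_series(cd.tukey_smooth(cooling_climate), ages)
    true = 0.3 * np.exp(-0.8 * T)
    rng = np.random.default_rng(2)
    slopes = []
    for _ in range(100):
        noisy = true + rng.normal(0.0, 0.01 * true.mean(), size=true.size)
        slopes.append(
            fit_rate_temperature_curve(ages, noisy, cooling_climate, window=10.0)["b"]
        )
    assert abs(np.median(slopes) - (-0.8)) < 0.08
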
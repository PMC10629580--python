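"""Birth-death diversification models with time- or environment-dependent
rates: likelihood, maximum-likelihood fitting, and AICc model comparison.

Model family
------------
Speciation and extinction rates are parametric functions of age ``t``
(My before present):

* ``constant``:  rate(t) = r0
* ``exp_time``:  rate(t) = r0 * exp(beta * t)
* ``exp_env``:   rate(t) = r0 * exp(alpha * T(t))

where ``T(t)`` is a paleoclimate proxy curve, Tukey-smoothed and linearly
interpolated (the same preprocessing used by the correlation analyses).
The working model set compares exponential speciation driven by time
against exponential speciation driven by the environment, each with no,
constant, or exponential extinction — six models.  Linear rate models are
deliberately excluded from the set: they are prone to pathological fits
over realistic covariate ranges and bias comparisons between the two
families.  Extinction enters only as a nuisance component of the fits; it
is never interpreted as an estimate of historical extinction.

Likelihood
----------
The reconstructed-process likelihood for a crown tree with sampling
fraction ``f``.  With ``r(t) = int_0^t (lambda(u) - mu(u)) du`` and
``g(t) = 1/f + int_0^t lambda(s) exp(r(s)) ds``:

* probability a lineage alive at age t leaves no sampled descendant:
  ``Phi(t) = 1 - exp(r(t)) / g(t)``
* per-edge kernel for an edge from age s (young) to t (old):
  ``Psi(s, t) = exp(r(t) - r(s)) * (g(s) / g(t))**2``

``logL = sum_i log lambda(t_i)`` over the n-1 internal nodes, plus
``sum_edges log Psi(s, t)`` over the 2n-2 crown-tree edges, plus
``n log f``.  Under crown-survival conditioning (the default) the crown
event is conditioned upon rather than observed, so the likelihood is
divided by ``lambda(t_crown) * (1 - Phi(t_crown))**2``; the result then
coincides with the classic constant-rate reconstructed-tree density when
rates are constant.  ``conditioning="none"`` keeps the raw product (used
by nesting and oracle tests).

Integrals are accumulated by cumulative Simpson quadrature on a dense
cached grid (default 2,000 points from the present to the crown age)
into which the tree's node ages are merged, so per-node values are read
off the grid exactly; doubling the grid changes logL by far less than
the optimizer tolerance, which the test suite checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import ConfigError, DataError, NumericalError
from .paleo_series import PaleoSeries, interpolate_series, smooth_if_possible
from .phylo_core import TimeTree

RateForm = Literal["constant", "exp_time", "exp_env"]

#: hard bounds on exponential slopes (per My, or per proxy unit)
SLOPE_BOUNDS = (-10.0, 10.0)
#: exponent cap above which the likelihood reports a numerical failure
MAX_LOG_RATE_INTEGRAL = 500.0
DEFAULT_GRID_SIZE = 2000


@dataclass(frozen=True)
class RateSpec:
    """Parametric rate function lambda(t) or mu(t)."""

    form: RateForm
    base: float
    slope: float = 0.0
    covariate: PaleoSeries | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.base) or not math.isfinite(self.slope):
            raise ConfigError("rate parameters must be finite")
        if self.form == "exp_env" and self.covariate is None:
            raise ConfigError("exp_env rate requires a covariate series")
        if self.form != "exp_env" and self.covariate is not None:
            raise ConfigError(f"covariate supplied for form {self.form!r}")

    def rate_at(self, ages: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous rate at the given age(s)."""
        ages = np.asarray(ages, dtype=float)
        if self.form == "constant":
            out = np.full_like(ages, self.base, dtype=float)
        elif self.form == "exp_time":
            out = self.base * np.exp(self.slope * ages)
        else:
            T = interpolate_series(smooth_if_possible(self.covariate), np.atleast_1d(ages))
            out = self.base * np.exp(self.slope * T).reshape(ages.shape)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class BDModel:
    """A speciation rate spec plus an optional extinction spec."""

    speciation: RateSpec
    extinction: RateSpec | None = None
    conditioning: Literal["none", "crown_survival"] = "crown_survival"
    name: str = ""

    @property
    def k(self) -> int:
        """Free-parameter count: 2 for exponential speciation alone,
        +1 for constant extinction, +2 for exponential extinction."""
        k = 1 if self.speciation.form == "constant" else 2
        if self.extinction is not None:
            k += 1 if self.extinction.form == "constant" else 2
        return k


@dataclass
class FitResult:
    model: BDModel
    estimates: dict[str, float]
    logL: float
    k: int
    n: int
    aicc: float
    converged: bool
    n_starts_used: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.model.name,
            "params": self.estimates,
            "logL": self.logL,
            "k": self.k,
            "AICc": self.aicc,
            "converged": self.converged,
        }


def rate_at(spec: RateSpec, age: float) -> float:
    """Module-level convenience wrapper around :meth:`RateSpec.rate_at`."""
    return float(spec.rate_at(age))


# ----------------------------------------------------------------------
class _LikelihoodWorkspace:
    """Grid, covariate values and tree summaries cached across evaluations.

    One workspace serves every model fitted to the same (tree, covariate)
    pair, which is what makes the multi-start six-model fit affordable.
    """

    def __init__(
        self,
        tree: TimeTree,
        covariate: PaleoSeries | None = None,
        grid_size: int = DEFAULT_GRID_SIZE,
    ):
        self.tree = tree
        self.f = tree.sampling_fraction
        self.n = tree.n_tips
        self.t_c = tree.crown_age
        from .phylo_core import branching_times

        self.node_ages = branching_times(tree)  # n-1 ages, incl. crown
        edges = tree.edges(crown_only=True)
        self.edge_young = edges[:, 0]
        self.edge_old = edges[:, 1]
        # the node ages join the quadrature grid, so r(t) and g(t) are read
        # off grid nodes exactly instead of being re-interpolated (the
        # interpolation error would dominate the quadrature error)
        self.grid = np.union1d(np.linspace(0.0, self.t_c, grid_size), self.node_ages)
        self.node_idx = np.searchsorted(self.grid, self.node_ages)
        self.edge_young_idx = np.searchsorted(self.grid, self.edge_young)
        self.edge_old_idx = np.searchsorted(self.grid, self.edge_old)
        if covariate is not None:
            # clamped interpolation covers the tree span even if the proxy
            # does not; the smoother runs once here
            self.T_grid = interpolate_series(smooth_if_possible(covariate), self.grid)
        else:
            self.T_grid = None

    def _grid_rate(self, form: RateForm, base: float, slope: float) -> np.ndarray:
        if form == "constant":
            return np.full_like(self.grid, base)
        if form == "exp_time":
            return base * np.exp(np.clip(slope * self.grid, -700, 700))
        if self.T_grid is None:
            raise ConfigError("exp_env rate requires a covariate series")
        return base * np.exp(np.clip(slope * self.T_grid, -700, 700))

    def log_likelihood(
        self,
        lam_form: RateForm,
        lam_base: float,
        lam_slope: float,
        mu_form: RateForm | None,
        mu_base: float,
        mu_slope: float,
        conditioning: str = "crown_survival",
    ) -> float:
        lam = self._grid_rate(lam_form, lam_base, lam_slope)
        mu = (
            self._grid_rate(mu_form, mu_base, mu_slope)
            if mu_form is not None
            else np.zeros_like(lam)
        )
        net = lam - mu
        # r(t) = int_0^t (lambda - mu), cumulative Simpson for O(h^4) accuracy
        r = integrate.cumulative_simpson(net, x=self.grid, initial=0.0)
        if np.max(np.abs(r)) > MAX_LOG_RATE_INTEGRAL:
            raise NumericalError(
                "net-diversification integral overflow; parameters degenerate"
            )
        integrand = lam * np.exp(r)
        I = integrate.cumulative_simpson(integrand, x=self.grid, initial=0.0)
        g = 1.0 / self.f + I
        with np.errstate(invalid="ignore", divide="ignore"):
            # Simpson can locally overshoot on near-degenerate parameter
            # proposals; the resulting non-finite logL is rejected below
            log_g = np.log(g)

        r_young = r[self.edge_young_idx]
        r_old = r[self.edge_old_idx]
        lg_young = log_g[self.edge_young_idx]
        lg_old = log_g[self.edge_old_idx]

        lam_nodes = lam[self.node_idx]
        if np.any(lam_nodes <= 0) or not np.all(np.isfinite(lam_nodes)):
            return -np.inf

        log_psi = (r_old - r_young) + 2.0 * (lg_young - lg_old)
        logL = (
            float(np.sum(np.log(lam_nodes)))
            + float(np.sum(log_psi))
            + self.n * math.log(self.f)
        )
        if conditioning == "crown_survival":
            # divide by lambda(t_c) * (1 - Phi(t_c))^2: the crown event is
            # conditioned upon, not observed, so its rate factor must not
            # reward models with a huge crown-age speciation rate;
            # log(1 - Phi(t_c)) = r(t_c) - log g(t_c), no cancellation
            logL -= 2.0 * (r[-1] - log_g[-1]) + math.log(lam_nodes[0])
        if not math.isfinite(logL):
            raise NumericalError("non-finite log-likelihood")
        return logL


def bd_log_likelihood(
    tree: TimeTree, model: BDModel, grid_size: int = DEFAULT_GRID_SIZE
) -> float:
    """Log-likelihood of ``model`` on ``tree`` (see module docstring)."""
    cov = None
    if model.speciation.form == "exp_env":
        cov = model.speciation.covariate
    elif model.extinction is not None and model.extinction.form == "exp_env":
        cov = model.extinction.covariate
    ws = _LikelihoodWorkspace(tree, covariate=cov, grid_size=grid_size)
    ext = model.extinction
    return ws.log_likelihood(
        model.speciation.form,
        model.speciation.base,
        model.speciation.slope,
        None if ext is None else ext.form,
        0.0 if ext is None else ext.base,
        0.0 if ext is None else ext.slope,
        conditioning=model.conditioning,
    )


# ----------------------------------------------------------------------
# maximum-likelihood fitting


def _model_layout(model: BDModel) -> list[tuple[str, str]]:
    """Ordered free parameters as (name, kind) with kind in {log, slope}."""
    layout: list[tuple[str, str]] = [("lambda0", "log")]
    if model.speciation.form != "constant":
        layout.append(("lambda_slope", "slope"))
    if model.extinction is not None:
        layout.append(("mu0", "log"))
        if model.extinction.form != "constant":
            layout.append(("mu_slope", "slope"))
    return layout


def fit_model(
    tree: TimeTree,
    model: BDModel,
    n_starts: int = 5,
    seed: int = 0,
    grid_size: int = DEFAULT_GRID_SIZE,
    workspace: _LikelihoodWorkspace | None = None,
    extra_starts: Sequence[dict[str, float]] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of ``model`` by multi-start Nelder-Mead.

    Base rates are optimized on the log scale (positivity by
    construction); slopes are box-constrained to ``SLOPE_BOUNDS`` via a
    soft rejection.  Starts are deterministic given ``seed``; the fit with
    the best converged objective wins.  ``extra_starts`` allows warm
    starts, e.g. estimates of a nested model (missing parameters fall
    back to the default start).
    """
    if tree.n_tips < 3:
        raise DataError("model fitting needs at least 3 tips")
    if workspace is None:
        cov = None
        if model.speciation.form == "exp_env":
            cov = model.speciation.covariate
        elif model.extinction is not None and model.extinction.form == "exp_env":
            cov = model.extinction.covariate
        workspace = _LikelihoodWorkspace(tree, covariate=cov, grid_size=grid_size)
    layout = _model_layout(model)
    lam_form = model.speciation.form
    mu_form = None if model.extinction is None else model.extinction.form
    conditioning = model.conditioning

    def unpack(theta: np.ndarray) -> dict[str, float]:
        params = {"lambda_slope": 0.0, "mu0": 0.0, "mu_slope": 0.0}
        for val, (pname, kind) in zip(theta, layout):
            params[pname] = math.exp(val) if kind == "log" else val
        return params

    def neg_logL(theta: np.ndarray) -> float:
        for val, (_, kind) in zip(theta, layout):
            if kind == "slope" and not SLOPE_BOUNDS[0] <= val <= SLOPE_BOUNDS[1]:
                return 1e10
            if kind == "log" and abs(val) > 50:
                return 1e10
        p = unpack(theta)
        try:
            ll = workspace.log_likelihood(
                lam_form, p["lambda0"], p["lambda_slope"],
                mu_form, p["mu0"], p["mu_slope"],
                conditioning=conditioning,
            )
        except NumericalError:
            return 1e10
        return -ll if math.isfinite(ll) else 1e10

    # moment-based anchor: Yule-like rate from tips and total branch length
    lam_anchor = max((tree.n_tips - 1) / tree.total_branch_length(), 1e-4)
    rng = np.random.default_rng(seed)
    starts = []
    base_start = []
    for pname, kind in layout:
        if pname == "lambda0":
            base_start.append(math.log(lam_anchor))
        elif pname == "mu0":
            base_start.append(math.log(lam_anchor * 0.2))
        else:
            base_start.append(0.0)
    starts.append(np.array(base_start))
    if model.extinction is not None:
        # high-turnover start: mu near lambda, mild positive slopes; the
        # likelihood surface of extinction-bearing models has a turnover
        # ridge that slope-zero starts routinely miss
        s = np.array(base_start)
        for i, (pname, kind) in enumerate(layout):
            if pname == "mu0":
                s[i] = math.log(lam_anchor * 0.8)
            elif kind == "slope":
                s[i] = 0.05
        starts.append(s)
    for d in extra_starts or ():
        s = np.array(base_start)
        for i, (pname, kind) in enumerate(layout):
            if pname in d:
                s[i] = math.log(max(d[pname], 1e-8)) if kind == "log" else d[pname]
        starts.append(s)
    for _ in range(n_starts - 1):
        jitter = rng.normal(scale=0.5, size=len(layout))
        slope_jitter = rng.uniform(-0.3, 0.3, size=len(layout))
        s = np.array(base_start)
        for i, (_, kind) in enumerate(layout):
            s[i] += jitter[i] if kind == "log" else slope_jitter[i]
        starts.append(s)

    best = None
    failures = []
    n_used = 0
    for s in starts:
        n_used += 1
        res = optimize.minimize(
            neg_logL,
            s,
            method="Nelder-Mead",
            options={
                "maxiter": 400 * len(layout),
                "xatol": 1e-6,
                "fatol": 1e-8,
            },
        )
        if res.fun >= 1e9:
            failures.append(s)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise NumericalError(
            f"all {len(starts)} optimizer starts failed: {failures}"
        )
    params = unpack(best.x)
    estimates = {name: params[name] for name, _ in layout}
    logL = -float(best.fun)
    k = model.k
    aicc = aicc_value(logL, k, tree.n_tips)
    return FitResult(
        model=model,
        estimates=estimates,
        logL=logL,
        k=k,
        n=tree.n_tips,
        aicc=aicc,
        converged=bool(best.success),
        n_starts_used=n_used,
    )


def aicc_value(logL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise DataError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * logL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc_weights(fits: Sequence[FitResult]) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AICc and Akaike weights across a candidate set fitted to one tree."""
    if len({fit.n for fit in fits}) != 1:
        raise DataError("AICc weights require fits on the same tree (same n)")
    aicc = np.array([fit.aicc for fit in fits])
    delta = aicc - aicc.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    return delta, w


def evidence_ratio(
    temp_fits: Sequence[FitResult], time_fits: Sequence[FitResult]
) -> float:
    """Summed Akaike weight of the environment-driven family over the
    time-driven family, weights computed jointly across all six fits.
    Values above 1 favor the environmental covariate."""
    fits = list(temp_fits) + list(time_fits)
    _, w = aicc_weights(fits)
    w_temp = float(np.sum(w[: len(temp_fits)]))
    w_time = float(np.sum(w[len(temp_fits):]))
    return w_temp / w_time


# ----------------------------------------------------------------------
def candidate_models(
    covariate: PaleoSeries,
    conditioning: Literal["none", "crown_survival"] = "crown_survival",
) -> tuple[list[BDModel], list[BDModel]]:
    """The six-model comparison set: exponential speciation driven by the
    environment or by time, each with no, constant, or exponential
    extinction.  Parameter values in the specs are placeholders; the
    fitter estimates them."""

    def lam(form: RateForm) -> RateSpec:
        return RateSpec(form, 0.1, 0.0, covariate if form == "exp_env" else None)

    def mu(form: RateForm | None) -> RateSpec | None:
        if form is None:
            return None
        return RateSpec(form, 0.05, 0.0, covariate if form == "exp_env" else None)

    temp = [
        BDModel(lam("exp_env"), mu(None), conditioning, name="env_spec_no_ext"),
        BDModel(lam("exp_env"), mu("constant"), conditioning, name="env_spec_const_ext"),
        BDModel(lam("exp_env"), mu("exp_env"), conditioning, name="env_spec_env_ext"),
    ]
    time = [
        BDModel(lam("exp_time"), mu(None), conditioning, name="time_spec_no_ext"),
        BDModel(lam("exp_time"), mu("constant"), conditioning, name="time_spec_const_ext"),
        BDModel(lam("exp_time"), mu("exp_time"), conditioning, name="time_spec_exp_ext"),
    ]
    return temp, time


def fit_candidate_models(
    tree: TimeTree,
    covariate: PaleoSeries,
    n_starts: int = 5,
    seed: int = 0,
    grid_size: int = DEFAULT_GRID_SIZE,
    conditioning: Literal["none", "crown_survival"] = "crown_survival",
) -> dict:
    """Fit the six-model set to one tree and summarize the comparison.

    Returns a dict with per-model fit tables (params, logL, k, AICc,
    dAICc, weight) and the family evidence ratio.
    """
    temp_models, time_models = candidate_models(covariate, conditioning)
    ws_env = _LikelihoodWorkspace(tree, covariate=covariate, grid_size=grid_size)
    ws_time = _LikelihoodWorkspace(tree, covariate=None, grid_size=grid_size)
    fits: list[FitResult] = []
    for models, ws in ((temp_models, ws_env), (time_models, ws_time)):
        warm: list[dict[str, float]] = []
        for m in models:  # no_ext -> const_ext -> exp_ext: warm-start chain
            fit = fit_model(
                tree, m, n_starts, seed, workspace=ws, extra_starts=warm
            )
            warm = warm + [fit.estimates]
            fits.append(fit)
    delta, w = aicc_weights(fits)
    er = float(np.sum(w[:3]) / np.sum(w[3:]))
    table = []
    for fit, d, wi in zip(fits, delta, w):
        row = fit.to_dict()
        row["dAICc"] = float(d)
        row["weight"] = float(wi)
        table.append(row)
    best = table[int(np.argmin([f.aicc for f in fits]))]["name"]
    return {
        "models": table,
        "evidence_ratio_env_vs_time": er,
        "best_model": best,
        "n_tips": tree.n_tips,
        "sampling_fraction": tree.sampling_fraction,
    }


# ----------------------------------------------------------------------
def fit_rate_temperature_curve(
    rtt_ages: np.ndarray,
    rtt_rates: np.ndarray,
    climate: PaleoSeries,
    window: float = 10.0,
) -> dict:
    """Least-squares exponential fit rate = a * exp(b * T) within an age window.

    The climate proxy is smoothed and interpolated onto the rate grid
    restricted to ages <= ``window`` (My).  Returns a > 0, b, and R^2 of
    the exponential fit.  Initialized from the log-linear regression and
    refined by nonlinear least squares.
    """
    rtt_ages = np.asarray(rtt_ages, dtype=float)
    rtt_rates = np.asarray(rtt_rates, dtype=float)
    mask = rtt_ages <= window
    if mask.sum() < 3:
        raise DataError(
            f"need >= 3 rate points within the {window} My window, got {mask.sum()}"
        )
    ages = rtt_ages[mask]
    rates = rtt_rates[mask]
    if np.any(rates <= 0):
        raise DataError("rates must be positive for an exponential fit")
    T = interpolate_series(smooth_if_possible(climate), ages)
    # log-linear initialization (exact when noiseless)
    b0, loga0 = np.polyfit(T, np.log(rates), 1)
    if np.allclose(rates, rates[0]):
        a, b = float(rates[0]), 0.0
    else:
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x),
                T,
                rates,
                p0=[math.exp(loga0), b0],
                maxfev=10000,
            )
            a, b = float(popt[0]), float(popt[1])
        except RuntimeError as exc:  # pragma: no cover - pathological inputs
            raise NumericalError(f"exponential curve fit failed: {exc}") from exc
    pred = a * np.exp(b * T)
    ss_res = float(np.sum((rates - pred) ** 2))
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"a": a, "b": b, "r2": r2, "n_points": int(mask.sum())}
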
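"""Synthetic inputs with the statistical structure the analyses assume.

Every input the pipeline consumes can be generated here: trees grown
forward under time- or environment-dependent birth-death rates with
incomplete sampling, a monotone-cooling climate proxy with oscillation
and noise, posterior-like rate-through-time ensembles around a known true
curve, Brownian and threshold-binary traits, clade-painted rate regimes,
and clustered occurrence points per species.  All generators draw from a
single seeded ``numpy`` generator per call and are bit-reproducible.

The tree simulator uses thinning: within 1-My windows an upper bound of
1.1 x the window maximum of lambda(t) + mu(t) dominates the true event
rate, proposed events are accepted by the true rates, extinct lineages
are pruned, and extant tips are binomially subsampled with the sampling
fraction f.  Replicates are rejected and redrawn until the sampled tip
count falls in the configured window and both crown lineages survive
(the likelihood's crown-survival conditioning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bd_models import RateSpec
from .errors import ConfigError, DataError, NumericalError
from .paleo_series import PaleoSeries, interpolate_series, smooth_if_possible
from .phylo_core import TimeTree, parse_newick

MAX_LINEAGES = 100_000
MAX_REJECTS = 1000


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ClimateScenario:
    """Monotone trend + sinusoidal oscillation + white noise, emulating a
    long-term cooling proxy.  ``start`` is the value at the oldest age
    (``span`` My), ``end`` the present-day value.

    ``trend_curvature`` bends the monotone trend: 0 gives the straight
    line between ``end`` and ``start``; positive values concentrate the
    change near the present (flat warm deep past, steep recent cooling,
    the shape of the Cenozoic benthic oxygen-isotope stack).  The bend is
    ``s(u) = (1 - exp(-k u)) / (1 - exp(-k))`` of the age fraction u.

    ``oscillation_recency`` in [0, 1] shrinks the oscillation amplitude
    linearly with age: 0 keeps it constant, 1 fades it to zero at the
    oldest age.  The real record's My-scale oscillations are largest in
    the Plio-Pleistocene and nearly absent in the early Cenozoic.
    """

    start: float = 5.0
    end: float = 0.0
    oscillation_amplitude: float = 0.5
    oscillation_period: float = 8.0
    noise_sd: float = 0.15
    step: float = 0.5
    span: float = 65.0
    trend_curvature: float = 0.0
    oscillation_recency: float = 0.0

    def __post_init__(self) -> None:
        if self.span <= 0 or self.step <= 0:
            raise ConfigError("span and step must be positive")
        if self.noise_sd < 0 or self.oscillation_amplitude < 0:
            raise ConfigError("noise sd and amplitude must be >= 0")
        if not 0.0 <= self.oscillation_recency <= 1.0:
            raise ConfigError("oscillation_recency must be in [0, 1]")


def simulate_climate(scn: ClimateScenario, seed: int = 0) -> PaleoSeries:
    """Deterministic given the seed; with zero amplitude and zero noise the
    series is exactly the linear trend between ``end`` (present) and
    ``start`` (oldest age)."""
    rng = np.random.default_rng(seed)
    n = int(round(scn.span / scn.step)) + 1
    ages = np.linspace(0.0, scn.span, n)
    u = ages / scn.span
    k = scn.trend_curvature
    bend = u if k == 0 else -np.expm1(-k * u) / -np.expm1(-k)
    trend = scn.end + (scn.start - scn.end) * bend
    if scn.oscillation_amplitude > 0:
        amp = scn.oscillation_amplitude * (1.0 - scn.oscillation_recency * u)
        osc = amp * np.sin(2 * np.pi * ages / scn.oscillation_period)
    else:
        osc = 0.0
    noise = rng.normal(0.0, scn.noise_sd, size=n) if scn.noise_sd > 0 else 0.0
    return PaleoSeries(ages, trend + osc + noise, unit="proxy", name="synthetic")


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SimConfig:
    """Generative birth-death settings for one tree replicate."""

    speciation: RateSpec
    extinction: RateSpec | None = None
    crown_age: float = 65.0
    sampling_fraction: float = 1.0
    min_tips: int = 2
    max_tips: int = 100_000

    def __post_init__(self) -> None:
        if not 0 < self.sampling_fraction <= 1:
            raise ConfigError("sampling fraction must be in (0, 1]")
        if self.crown_age <= 0:
            raise ConfigError("crown age must be positive")
        if self.min_tips < 0 or self.max_tips < self.min_tips:
            raise ConfigError("invalid tip-count window")


@dataclass
class RawSimOutcome:
    """One forward simulation before any accept/reject decision."""

    n_extant: int
    n_sampled: int
    crown_ok: bool  # both crown lineages have sampled descendants
    newick: str | None  # reconstructed sampled tree, None if < 2 sampled tips


def _rate_grid(
    spec: RateSpec | None, ages: np.ndarray, smoothed_cov: np.ndarray | None
) -> np.ndarray:
    if spec is None:
        return np.zeros_like(ages)
    if spec.form == "constant":
        return np.full_like(ages, spec.base)
    if spec.form == "exp_time":
        return spec.base * np.exp(spec.slope * ages)
    return spec.base * np.exp(spec.slope * smoothed_cov)


def _true_rates(cfg: SimConfig, grid_points: int = 400):
    ages = np.linspace(0.0, cfg.crown_age, grid_points)
    cov = None
    for spec in (cfg.speciation, cfg.extinction):
        if spec is not None and spec.form == "exp_env":
            if spec.covariate is None:
                raise ConfigError("exp_env simulation requires a covariate")
            cov = interpolate_series(smooth_if_possible(spec.covariate), ages)
            break
    lam = _rate_grid(cfg.speciation, ages, cov)
    mu = _rate_grid(cfg.extinction, ages, cov)
    return ages, lam, mu


def simulate_bd_forward(cfg: SimConfig, rng: np.random.Generator) -> RawSimOutcome:
    """One unconditioned forward pass (see module docstring).

    Exposed separately from :func:`simulate_bd_tree` so branching-process
    expectations (mean tip counts, f-thinning) can be checked without the
    accept/reject conditioning.
    """
    ages_grid, lam_grid, mu_grid = _true_rates(cfg)
    tc = cfg.crown_age

    def lam(age: float) -> float:
        return float(np.interp(age, ages_grid, lam_grid))

    def mu(age: float) -> float:
        return float(np.interp(age, ages_grid, mu_grid))

    # node bookkeeping; node 0 is the crown, its two children start lineages
    parent = [-1, 0, 0]
    start_age = [tc, tc, tc]  # age at which the lineage (edge) begins
    end_age = [tc, None, None]  # age at which it ends (speciation/extinction/0)
    children: list[list[int]] = [[1, 2], [], []]
    alive = [1, 2]

    age = tc
    while alive and age > 1e-12:
        window_lo = max(0.0, math.ceil(age - 1e-12) - 1.0)
        total = lam_grid + mu_grid
        # widen by one grid node each side so linear interpolation between
        # nodes can never exceed the windowed maximum
        i_lo = max(0, int(np.searchsorted(ages_grid, window_lo)) - 1)
        i_hi = min(len(ages_grid), int(np.searchsorted(ages_grid, age)) + 2)
        bound = 1.1 * float(total[i_lo:i_hi].max())
        if bound <= 0:
            age = window_lo  # no events possible; jump the window
            continue
        while age > window_lo and alive:
            wait = rng.exponential(1.0 / (bound * len(alive)))
            if age - wait <= window_lo:
                age = window_lo
                break
            age -= wait
            lam_a, mu_a = lam(age), mu(age)
            if rng.random() >= (lam_a + mu_a) / bound:
                continue  # thinning rejection
            k = int(rng.integers(len(alive)))
            node = alive[k]
            if rng.random() < lam_a / (lam_a + mu_a):
                # speciation: close this edge, open two children
                end_age[node] = age
                for _ in range(2):
                    parent.append(node)
                    start_age.append(age)
                    end_age.append(None)
                    children.append([])
                    children[node].append(len(parent) - 1)
                alive[k] = len(parent) - 2
                alive.append(len(parent) - 1)
                if len(alive) > MAX_LINEAGES:
                    raise NumericalError(
                        f"lineage count exceeded {MAX_LINEAGES}; aborting replicate"
                    )
            else:
                end_age[node] = age  # extinction
                alive[k] = alive[-1]
                alive.pop()

    for node in alive:
        end_age[node] = 0.0
    extant = list(alive)
    sampled_mask = rng.random(len(extant)) < cfg.sampling_fraction
    sampled = [node for node, keep in zip(extant, sampled_mask) if keep]
    sampled_set = set(sampled)

    # propagate "has sampled descendant" rootward
    n_nodes = len(parent)
    has_sampled = [False] * n_nodes
    for node in sorted(sampled_set):
        has_sampled[node] = True
    for node in range(n_nodes - 1, 0, -1):  # children always have higher index
        if has_sampled[node]:
            has_sampled[parent[node]] = True
    crown_ok = len(children[0]) == 2 and all(has_sampled[c] for c in children[0])

    newick = None
    if len(sampled) >= 2 and crown_ok:
        newick = _reconstructed_newick(end_age, children, has_sampled)
    return RawSimOutcome(
        n_extant=len(extant),
        n_sampled=len(sampled),
        crown_ok=crown_ok,
        newick=newick,
    )


def _reconstructed_newick(end_age, children, has_sampled):
    """Newick of the sampled tree: unary chains collapsed, tip labels t<i>."""
    reps: dict[int, tuple[str, float]] = {}
    # iterative postorder over nodes with sampled descendants
    stack = [(0, False)]
    while stack:
        node, expanded = stack.pop()
        kids = [c for c in children[node] if has_sampled[c]]
        if not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in kids)
            continue
        if not kids:  # sampled tip
            reps[node] = (f"t{node}", 0.0)
        elif len(kids) == 1:
            reps[node] = reps.pop(kids[0])  # collapse unary chain
        else:
            parts = []
            node_age = end_age[node]
            for c in kids:
                s, child_age = reps.pop(c)
                parts.append(f"{s}:{node_age - child_age:.12g}")
            reps[node] = ("(" + ",".join(parts) + ")", node_age)
    s, _ = reps[0]
    return s + ";"


def simulate_bd_tree(
    cfg: SimConfig, seed: int = 0, truth_grid_points: int = 200
) -> tuple[TimeTree, dict]:
    """Simulate until a replicate passes the tip-count window with both
    crown lineages sampled; returns the tree and the true rate curves.

    Raises
    ------
    NumericalError
        After ``MAX_REJECTS`` rejected replicates.
    """
    rng = np.random.default_rng(seed)
    for attempt in range(MAX_REJECTS + 1):
        try:
            out = simulate_bd_forward(cfg, rng)
        except NumericalError:
            continue  # lineage-count blow-up aborts this replicate only
        if (
            out.newick is not None
            and cfg.min_tips <= out.n_sampled <= cfg.max_tips
        ):
            tree = parse_newick(out.newick, f=cfg.sampling_fraction)
            ages, lam, mu = _true_rates(cfg, truth_grid_points)
            truth = {
                "ages": ages,
                "lambda": lam,
                "mu": mu,
                "n_extant": out.n_extant,
                "n_sampled": out.n_sampled,
                "attempts": attempt + 1,
            }
            return tree, truth
    raise NumericalError(
        f"simulation rejected {MAX_REJECTS} replicates without hitting the "
        f"tip window [{cfg.min_tips}, {cfg.max_tips}]"
    )


# ----------------------------------------------------------------------
def simulate_rtt_ensemble(
    ages: np.ndarray,
    true_curve: np.ndarray,
    n_samples: int,
    noise_sd: float,
    seed: int = 0,
    source: str = "synthetic",
):
    """Posterior-like ensemble: each entry of each row is the true curve
    times a mean-one lognormal factor (sd ~ noise_sd for small noise).
    Zero noise returns rows identical to the truth."""
    from .dcca_stats import RTTEnsemble

    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    ages = np.asarray(ages, dtype=float)
    true_curve = np.asarray(true_curve, dtype=float)
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        rates = np.tile(true_curve, (n_samples, 1))
    else:
        sigma = math.sqrt(math.log(1.0 + noise_sd**2))
        factors = rng.lognormal(-0.5 * sigma**2, sigma, size=(n_samples, len(ages)))
        rates = true_curve[None, :] * factors
    return RTTEnsemble(ages, rates, source=source)


# ----------------------------------------------------------------------
def simulate_traits(
    tree: TimeTree,
    kind: str,
    seed: int = 0,
    sigma2: float = 1.0,
    prevalence: float = 0.5,
    n_regimes: int = 5,
    rate_range: tuple[float, float] = (0.05, 0.5),
):
    """Per-tip trait values for test nulls and power checks.

    ``bm``: Brownian motion with rate ``sigma2`` (returns an array).
    ``threshold_binary``: BM thresholded at the sample quantile giving the
    target prevalence (returns a 0/1 array).
    ``regime_rates``: ``n_regimes`` rate regimes painted on clades, each a
    distinct rate log-spaced in ``rate_range`` (returns values, labels).
    """
    from .tip_rate_tests import BMSimulator

    rng = np.random.default_rng(seed)
    n = tree.n_tips
    if kind == "bm":
        return BMSimulator(tree).simulate(sigma2, rng, n=1)[0]
    if kind == "threshold_binary":
        if not 0.0 < prevalence < 1.0:
            raise ConfigError("prevalence must be strictly between 0 and 1")
        x = BMSimulator(tree).simulate(sigma2, rng, n=1)[0]
        cut = np.quantile(x, 1.0 - prevalence)
        return (x >= cut).astype(int)
    if kind == "regime_rates":
        labels = np.zeros(n, dtype=int)
        internal = [
            i for i in range(len(tree.children)) if len(tree.children[i]) == 2
            and i != tree.crown_index
        ]
        tip_pos = {int(node): i for i, node in enumerate(tree.tip_index)}
        for regime in range(1, n_regimes):
            if not internal:
                break
            node = internal[int(rng.integers(len(internal)))]
            for nd in tree._postorder(node):
                if not tree.children[nd]:
                    labels[tip_pos[nd]] = regime
        present = np.unique(labels)
        relabel = {g: i for i, g in enumerate(present)}
        labels = np.array([relabel[g] for g in labels])
        rates = np.geomspace(rate_range[0], rate_range[1], num=max(len(present), 1))
        rates = rng.permutation(rates)
        return rates[labels], labels
    raise ConfigError(f"unknown trait kind {kind!r}")


# ----------------------------------------------------------------------
REGION_CENTERS = {
    "Africa": (22.0, -4.0),
    "Australia": (134.0, -25.0),
    "Eurasia": (60.0, 48.0),
    "North America": (-100.0, 42.0),
    "Neotropics": (-65.0, -12.0),
    "Pacific": (-155.0, -16.0),
    "Southeast Asia": (105.0, 8.0),
}


def simulate_occurrences(
    species_regions: dict[str, str],
    region_centers: dict[str, tuple[float, float]] | None = None,
    spread_deg: float = 2.0,
    n_per_species: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian occurrence scatter around each species' region center,
    clipped to valid lon/lat; exactly ``n_per_species`` rows per species."""
    if n_per_species < 1:
        raise ConfigError("n_per_species must be >= 1")
    centers = region_centers or REGION_CENTERS
    rng = np.random.default_rng(seed)
    rows = []
    for sp in sorted(species_regions):
        region = species_regions[sp]
        if region not in centers:
            raise DataError(f"no center for region {region!r}")
        lon0, lat0 = centers[region]
        lon = np.clip(rng.normal(lon0, spread_deg, n_per_species), -180.0, 180.0)
        lat = np.clip(rng.normal(lat0, spread_deg, n_per_species), -90.0, 90.0)
        for x, y in zip(lon, lat):
            rows.append({"species": sp, "lon": float(x), "lat": float(y)})
    return pd.DataFrame(rows)
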
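"""Phylogenetically-corrected association tests between tip speciation
rates and species covariates, plus binary-trait phylogenetic signal.

Tip-rate proxies
----------------
The equal-splits statistic for tip i is ``ES_i = sum_j l_j * 2**-(j-1)``
over the edges on the tip-to-root path, j = 1 at the tip edge; its
inverse, DR = 1/ES, is the usual tip speciation-rate proxy.

Tests
-----
* ``essim_test`` — observed Pearson correlation between a continuous
  trait and log(DR); the null distribution is the same statistic on
  Brownian-motion simulations of the trait along the tree (BM variance
  estimated by ML from the observed trait).
* ``strapp_test`` — structured rate permutations: tip rates are constant
  within rate regimes, and the null shuffles the regime -> rate-value
  assignment while every regime keeps its tips, which nulls out
  phylogenetic pseudoreplication without re-fitting rate models.  The
  association statistic is Spearman correlation (continuous traits),
  Mann-Whitney U (binary), or Kruskal-Wallis H (categorical).
* ``d_statistic`` — Fritz-Purvis signal for a binary trait:
  D = (d_obs - mean d_BM) / (mean d_random - mean d_BM), where d sums
  sister-clade differences of the (recursively averaged) trait, d_random
  comes from shuffling tip states, and d_BM from threshold-discretized
  Brownian simulations at the observed prevalence.  D is ~1 for a random
  trait, ~0 for Brownian clumping, and negative for hyper-clumping.

All permutation p-values use the add-one estimator
``p = (1 + #exceedances) / (1 + n_perm)``, which never returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .phylo_core import TimeTree


@dataclass
class TestReport:
    statistic_name: str
    statistic: float
    p_value: float
    n_resamples: int
    tail: str
    extras: dict | None = None

    def to_dict(self) -> dict:
        out = {
            "statistic": self.statistic_name,
            "value": self.statistic,
            "p": self.p_value,
            "n_resamples": self.n_resamples,
            "tail": self.tail,
        }
        if self.extras:
            out.update(self.extras)
        return out


@dataclass
class TipTable:
    """Per-species tip rates, regimes, and covariates, aligned to tree tips."""

    df: pd.DataFrame  # index: species

    REQUIRED = ("tip_rate",)

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise DataError(f"tip table missing required column {col!r}")
        if np.any(self.df["tip_rate"].to_numpy(float) <= 0):
            raise DataError("tip rates must be > 0")
        if self.df.index.duplicated().any():
            raise DataError("duplicate species in tip table")

    @classmethod
    def read_csv(cls, path: str) -> "TipTable":
        df = pd.read_csv(path)
        if "species" not in df.columns:
            raise DataError(f"{path}: missing 'species' column")
        return cls(df.set_index("species"))

    def aligned_to(self, tree: TimeTree) -> "TipTable":
        missing = set(tree.tip_labels) - set(self.df.index)
        if missing:
            raise DataError(f"tip table missing {len(missing)} tree tips: "
                            f"{sorted(missing)[:5]}...")
        return TipTable(self.df.loc[list(tree.tip_labels)])

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise DataError(f"tip table has no column {name!r}")
        return self.df[name].to_numpy()


# ----------------------------------------------------------------------
def es_statistic(tree: TimeTree) -> pd.DataFrame:
    """Equal-splits statistic and DR = 1/ES per tip.

    The tip-to-root path includes a stem edge when the tree has one;
    symmetric tips receive identical values.
    """
    es = np.zeros(tree.n_tips)
    for i, node in enumerate(tree.tip_index):
        j = 0
        nd = int(node)
        total = 0.0
        while tree.parent[nd] >= 0:
            total += tree.edge_length[nd] * 2.0 ** (-j)
            nd = int(tree.parent[nd])
            j += 1
        es[i] = total
    return pd.DataFrame({"ES": es, "DR": 1.0 / es}, index=tree.tip_labels)


# ----------------------------------------------------------------------
# Brownian-motion machinery shared by Es-Sim and the D statistic


class BMSimulator:
    """Brownian trait simulation on a fixed tree via the Cholesky factor
    of the tip covariance matrix (shared root-to-MRCA path lengths)."""

    def __init__(self, tree: TimeTree):
        self.tree = tree
        C = tree.vcv()
        # jitter for numerically singular cherries is unnecessary: positive
        # branch lengths guarantee positive definiteness
        self.chol = np.linalg.cholesky(C)
        self._C = C

    def simulate(self, sigma2: float, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        z = rng.standard_normal((n, self.tree.n_tips))
        return np.sqrt(sigma2) * (z @ self.chol.T)

    def ml_sigma2(self, trait: np.ndarray) -> float:
        """ML estimate of the BM rate given the tree covariance, with the
        root state profiled out (GLS mean)."""
        Cinv_x = np.linalg.solve(self._C, trait)
        ones = np.ones_like(trait)
        Cinv_1 = np.linalg.solve(self._C, ones)
        mu = float(ones @ Cinv_x) / float(ones @ Cinv_1)
        resid = trait - mu
        return float(resid @ np.linalg.solve(self._C, resid)) / len(trait)


def essim_test(
    tree: TimeTree,
    trait: np.ndarray,
    n_sim: int = 1000,
    seed: int = 0,
    simulator: BMSimulator | None = None,
) -> TestReport:
    """Es-Sim: Pearson correlation of a continuous trait with log(DR),
    calibrated against Brownian simulations of the trait on the tree."""
    trait = np.asarray(trait, dtype=float)
    if len(trait) != tree.n_tips:
        raise DataError("trait length must equal the number of tips")
    if np.ptp(trait) == 0:
        raise DataError("Es-Sim undefined for a constant trait")
    if n_sim < 100:
        raise DataError("n_sim must be >= 100")
    log_dr = np.log(es_statistic(tree)["DR"].to_numpy())
    obs = float(stats.pearsonr(trait, log_dr).statistic)
    sim = simulator if simulator is not None else BMSimulator(tree)
    sigma2 = sim.ml_sigma2(trait)
    rng = np.random.default_rng(seed)
    sims = sim.simulate(sigma2, rng, n=n_sim)
    # vectorized Pearson r of each simulated trait against log(DR)
    sims_c = sims - sims.mean(axis=1, keepdims=True)
    y_c = log_dr - log_dr.mean()
    null = (sims_c @ y_c) / (
        np.linalg.norm(sims_c, axis=1) * np.linalg.norm(y_c)
    )
    exceed = int(np.sum(np.abs(null) >= abs(obs)))
    p = (1 + exceed) / (1 + n_sim)
    return TestReport("pearson_r_vs_logDR", obs, p, n_sim, "two-sided")


# ----------------------------------------------------------------------
def _strapp_stat(rates: np.ndarray, trait: np.ndarray, stat: str) -> float:
    if stat == "spearman":
        return float(stats.spearmanr(rates, trait).statistic)
    if stat == "mann_whitney":
        groups = np.unique(trait)
        if len(groups) != 2:
            raise DataError("mann_whitney requires a binary trait")
        u = stats.mannwhitneyu(
            rates[trait == groups[0]], rates[trait == groups[1]]
        ).statistic
        n0 = int(np.sum(trait == groups[0]))
        n1 = int(np.sum(trait == groups[1]))
        # distance from the null mean, so larger = more extreme either way
        return float(abs(u - n0 * n1 / 2.0))
    if stat == "kruskal_wallis":
        groups = [rates[trait == g] for g in np.unique(trait)]
        if len(groups) < 2:
            raise DataError("kruskal_wallis requires >= 2 groups")
        return float(stats.kruskal(*groups).statistic)
    raise DataError(f"unknown STRAPP statistic {stat!r}")


def strapp_test(
    tips: TipTable,
    trait_column: str,
    stat: str = "spearman",
    n_perm: int = 1000,
    seed: int = 0,
) -> TestReport:
    """Structured rate permutation test of tip rate against a covariate.

    Tips within a rate regime share a rate value; the null shuffles which
    rate value each regime carries (regimes keep their tip sets), and the
    association statistic is recomputed.  With a single regime the
    statistic is permutation-invariant and p = 1 by construction.
    """
    if "regime" not in tips.df.columns:
        raise DataError("STRAPP requires a 'regime' column in the tip table")
    rates = tips.column("tip_rate").astype(float)
    regimes = tips.column("regime")
    trait = tips.column(trait_column)
    if np.issubdtype(np.asarray(trait).dtype, np.number) and np.ptp(trait) == 0:
        raise DataError("STRAPP undefined for a constant trait")
    uniq = pd.unique(regimes)
    obs = _strapp_stat(rates, trait, stat)
    if len(uniq) < 2:
        return TestReport(
            stat, obs, 1.0, 0, "permutation",
            extras={"warning": "single regime: statistic is permutation-invariant"},
        )
    # representative rate per regime (rates are constant within a regime;
    # if not exactly constant, the regime mean is used)
    regime_pos = {g: i for i, g in enumerate(uniq)}
    regime_idx = np.array([regime_pos[g] for g in regimes])
    regime_rates = np.array(
        [rates[regime_idx == i].mean() for i in range(len(uniq))]
    )
    rng = np.random.default_rng(seed)
    two_sided = stat == "spearman"
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(uniq))
        perm_rates = regime_rates[perm][regime_idx]
        s = _strapp_stat(perm_rates, trait, stat)
        if two_sided:
            if abs(s) >= abs(obs):
                exceed += 1
        else:
            if s >= obs:
                exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return TestReport(stat, obs, p, n_perm, "two-sided" if two_sided else "upper")


# ----------------------------------------------------------------------
def _sister_clade_d(tree: TimeTree, tip_values: np.ndarray) -> float:
    """Sum over internal nodes of |difference| between the two daughter
    clades' recursively averaged trait values."""
    vals: dict[int, float] = {}
    tip_pos = {int(node): i for i, node in enumerate(tree.tip_index)}
    total = 0.0
    for nd in tree._postorder(tree.crown_index):
        kids = tree.children[nd]
        if not kids:
            vals[nd] = float(tip_values[tip_pos[nd]])
        else:
            a, b = (vals.pop(k) for k in kids)
            total += abs(a - b)
            vals[nd] = 0.5 * (a + b)
    return total


def d_statistic(
    tree: TimeTree,
    binary_trait: np.ndarray,
    n_perm: int = 1000,
    n_sim: int = 1000,
    seed: int = 0,
    simulator: BMSimulator | None = None,
) -> TestReport:
    """Fritz-Purvis D for a binary tip trait (see module docstring).

    Also reports permutation p-values for departure from each reference
    distribution (random shuffles; thresholded Brownian).
    """
    trait = np.asarray(binary_trait).astype(float)
    if len(trait) != tree.n_tips:
        raise DataError("trait length must equal the number of tips")
    states = np.unique(trait)
    if len(states) != 2:
        raise DataError("D statistic requires both binary states present")
    if n_perm < 100 or n_sim < 100:
        raise DataError("n_perm and n_sim must be >= 100")
    prevalence = float(np.mean(trait == states[1]))
    indicator = (trait == states[1]).astype(float)
    d_obs = _sister_clade_d(tree, indicator)

    rng = np.random.default_rng(seed)
    d_random = np.array(
        [_sister_clade_d(tree, rng.permutation(indicator)) for _ in range(n_perm)]
    )
    sim = simulator if simulator is not None else BMSimulator(tree)
    bm = sim.simulate(1.0, rng, n=n_sim)
    # threshold each simulation at the quantile matching observed prevalence
    cuts = np.quantile(bm, 1.0 - prevalence, axis=1, keepdims=True)
    bm_states = (bm >= cuts).astype(float)
    d_bm = np.array([_sister_clade_d(tree, row) for row in bm_states])

    mean_rand = float(d_random.mean())
    mean_bm = float(d_bm.mean())
    if mean_rand == mean_bm:
        raise DataError("degenerate D references: random and Brownian means equal")
    D = (d_obs - mean_bm) / (mean_rand - mean_bm)
    p_random = (1 + int(np.sum(d_random <= d_obs))) / (1 + n_perm)
    p_bm = (1 + int(np.sum(d_bm >= d_obs))) / (1 + n_sim)
    return TestReport(
        "D", float(D), p_random, n_perm, "lower",
        extras={
            "d_obs": d_obs,
            "mean_d_random": mean_rand,
            "mean_d_bm": mean_bm,
            "p_vs_random": p_random,
            "p_vs_brownian": p_bm,
        },
    )


# ----------------------------------------------------------------------
TROPICAL_LATITUDE = 23.5
TROPICAL_TEMP_C = 18.0


def classify_tropical(
    occurrences: pd.DataFrame,
    mode: str = "latitude",
) -> tuple[pd.Series, list[str]]:
    """Strict-majority tropical classification per species.

    ``latitude`` mode: tropical when more than half of a species'
    occurrence localities lie within +/-23.5 degrees of the equator
    (the band boundary counts as inside).  ``temperature`` mode: tropical
    when the temperature at more than half of the localities exceeds
    18 C; requires a ``mean_temp_c`` column.  Exactly 50% is nontropical.
    Species without occurrences cannot appear; the second return value
    lists species dropped for missing data in temperature mode.
    """
    if "species" not in occurrences.columns:
        raise DataError("occurrence table needs a 'species' column")
    dropped: list[str] = []
    if mode == "latitude":
        if "lat" not in occurrences.columns:
            raise DataError("latitude mode needs a 'lat' column")
        flags = (
            occurrences.assign(inside=occurrences["lat"].abs() <= TROPICAL_LATITUDE)
            .groupby("species")["inside"]
            .mean()
            > 0.5
        )
    elif mode == "temperature":
        if "mean_temp_c" not in occurrences.columns:
            raise DataError("temperature mode needs a 'mean_temp_c' column")
        occ = occurrences.dropna(subset=["mean_temp_c"])
        dropped = sorted(
            set(occurrences["species"]) - set(occ["species"])
        )
        flags = (
            occ.assign(warm=occ["mean_temp_c"] > TROPICAL_TEMP_C)
            .groupby("species")["warm"]
            .mean()
            > 0.5
        )
    else:
        raise DataError(f"unknown mode {mode!r}")
    return flags.astype(int), dropped
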
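"""End-to-end orchestration: simulate inputs, fit the six-model set,
run the DCCA ensemble tests, the tip-rate association tests, and the
bioregion summaries, writing machine-readable JSON/CSV outputs plus a
run manifest with seed and input checksums.

Every stage reads files and a :class:`PipelineConfig`; nothing mutates
its inputs, and all randomness flows from the configured seed, so a rerun
with the same config and seed is byte-identical (the manifest carries no
timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bd_models import fit_candidate_models, fit_rate_temperature_curve
from .bioregions import (
    filter_endemics,
    grid_summary,
    grid_summary_frame,
    read_region_table,
    region_rtt_correlations,
)
from .dcca_stats import ensemble_climate_test, read_rtt_csv, write_rtt_csv
from .errors import ConfigError, DataError
from .paleo_series import read_series_csv, write_series_csv
from .phylo_core import read_newick_file
from .synthetic_data import (
    REGION_CENTERS,
    ClimateScenario,
    SimConfig,
    simulate_bd_tree,
    simulate_climate,
    simulate_occurrences,
    simulate_rtt_ensemble,
    simulate_traits,
)
from .tip_rate_tests import (
    TipTable,
    classify_tropical,
    d_statistic,
    es_statistic,
    essim_test,
    strapp_test,
)
from .bd_models import RateSpec

log = logging.getLogger("chronodiv")


@dataclass
class PipelineConfig:
    """Paths, analysis settings, and the master seed for one run."""

    out_dir: str
    tree: str | None = None
    climate: dict[str, str] = field(default_factory=dict)  # proxy name -> csv
    rtt: str | None = None
    tips: str | None = None
    occurrences: str | None = None
    regions: str | None = None
    region_rtt: dict[str, str] = field(default_factory=dict)  # region -> csv
    sampling_fraction: float = 1.0
    primary_proxy: str = "temperature"
    box_size: int | None = None
    n_perm: int = 1000
    n_sim: int = 1000
    n_starts: int = 5
    grid_size: int = 2000
    burnin_frac: float = 0.0
    max_age: float | None = None
    rate_temp_window: float = 10.0
    cell_area_km2: float = 200.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config must set out_dir")
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# the bundled synthetic scenario


def load_scenario(path: str | None = None) -> dict:
    """Load a simulation scenario YAML; defaults to the bundled
    orchid-like scenario (65 My crown, cooling proxy, f = 0.3)."""
    if path is None:
        from importlib import resources

        text = (
            resources.files("chronodiv").joinpath("data/orchid_like.yaml").read_text()
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def simulate_scenario(scenario: dict, out_dir: str, seed: int = 0) -> dict:
    """Generate every pipeline input for a scenario into ``out_dir``.

    Writes tree.nwk, climate.csv, rtt.csv, per-region rtt_<region>.csv,
    tips.csv, occurrences.csv, regions.csv, and truth.json; returns a
    config dict pointing at them.  Seeds for each generator are derived
    deterministically from the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(8) % (2**31)]

    clim_cfg = scenario.get("climate", {})
    scn = ClimateScenario(**clim_cfg)
    climate = simulate_climate(scn, seed=seeds[0])
    write_series_csv(climate, str(out / "climate.csv"))

    tree_cfg = scenario.get("tree", {})
    lam = RateSpec(
        "exp_env",
        tree_cfg.get("lambda0", 0.1),
        tree_cfg.get("alpha", -0.15),
        climate,
    )
    mu0 = tree_cfg.get("mu0", 0.0)
    mu = RateSpec("constant", mu0) if mu0 > 0 else None
    cfg = SimConfig(
        speciation=lam,
        extinction=mu,
        crown_age=tree_cfg.get("crown_age", 65.0),
        sampling_fraction=tree_cfg.get("f", 0.3),
        min_tips=tree_cfg.get("min_tips", 100),
        max_tips=tree_cfg.get("max_tips", 300),
    )
    tree, truth = simulate_bd_tree(cfg, seed=seeds[1])
    (out / "tree.nwk").write_text(tree.write_newick() + "\n", encoding="utf-8")

    rtt_cfg = scenario.get("rtt", {})
    grid_step = rtt_cfg.get("grid_step", 0.5)
    n_grid = int(cfg.crown_age / grid_step) + 1
    grid = np.linspace(0.0, cfg.crown_age, n_grid)
    true_lambda = np.interp(grid, truth["ages"], truth["lambda"])
    ens = simulate_rtt_ensemble(
        grid,
        true_lambda,
        n_samples=rtt_cfg.get("n_samples", 200),
        noise_sd=rtt_cfg.get("noise_sd", 0.1),
        seed=seeds[2],
    )
    write_rtt_csv(ens, str(out / "rtt.csv"))

    # traits, regimes, regions, occurrences
    rates, regimes = simulate_traits(
        tree, "regime_rates", seed=seeds[3],
        n_regimes=scenario.get("traits", {}).get("n_regimes", 8),
    )
    rng = np.random.default_rng(seeds[4])
    region_names = list(REGION_CENTERS)
    region_of = {
        sp: region_names[int(rng.integers(len(region_names)))]
        for sp in tree.tip_labels
    }
    occ = simulate_occurrences(
        region_of,
        spread_deg=scenario.get("occurrences", {}).get("spread_deg", 2.0),
        n_per_species=scenario.get("occurrences", {}).get("n_per_species", 10),
        seed=seeds[5],
    )
    occ.to_csv(out / "occurrences.csv", index=False)

    # ~10% of species get a second region (non-endemics)
    region_rows = [
        {"species": sp, "bioregion": region_of[sp]} for sp in tree.tip_labels
    ]
    for sp in tree.tip_labels:
        if rng.random() < scenario.get("regions", {}).get("multi_region_frac", 0.1):
            other = region_names[int(rng.integers(len(region_names)))]
            if other != region_of[sp]:
                region_rows.append({"species": sp, "bioregion": other})
    pd.DataFrame(region_rows).to_csv(out / "regions.csv", index=False)

    mean_abs_lat = occ.assign(al=occ["lat"]).groupby("species")["al"].mean()
    elev = rng.lognormal(6.0, 0.8, size=tree.n_tips)
    tips_df = pd.DataFrame(
        {
            "species": tree.tip_labels,
            "tip_rate": rates,
            "regime": regimes,
            "latitude": mean_abs_lat.loc[list(tree.tip_labels)].to_numpy(),
            "elevation_min": np.round(elev * 0.6, 1),
            "elevation_max": np.round(elev * 1.4, 1),
            "bioregion": [region_of[sp] for sp in tree.tip_labels],
        }
    )
    tips_df.to_csv(out / "tips.csv", index=False)

    # per-region posterior-like ensembles: region-scaled truth
    region_files = {}
    for i, region in enumerate(region_names):
        factor = 0.6 + 0.8 * (i / max(len(region_names) - 1, 1))
        ens_r = simulate_rtt_ensemble(
            grid,
            true_lambda * factor,
            n_samples=max(rtt_cfg.get("n_samples", 200) // 4, 20),
            noise_sd=rtt_cfg.get("noise_sd", 0.1),
            seed=seeds[6] + i,
        )
        fname = f"rtt_{region.replace(' ', '_')}.csv"
        write_rtt_csv(ens_r, str(out / fname))
        region_files[region] = str(out / fname)

    _write_json(
        out / "truth.json",
        {
            "lambda0": lam.base,
            "alpha": lam.slope,
            "mu0": mu0,
            "crown_age": cfg.crown_age,
            "sampling_fraction": cfg.sampling_fraction,
            "n_tips": tree.n_tips,
            "seed": seed,
        },
    )
    return {
        "tree": str(out / "tree.nwk"),
        "climate": {"temperature": str(out / "climate.csv")},
        "rtt": str(out / "rtt.csv"),
        "tips": str(out / "tips.csv"),
        "occurrences": str(out / "occurrences.csv"),
        "regions": str(out / "regions.csv"),
        "region_rtt": region_files,
        "sampling_fraction": cfg.sampling_fraction,
        "seed": seed,
    }


# ----------------------------------------------------------------------
# stages


def stage_fit(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.tree is None or cfg.primary_proxy not in cfg.climate:
        raise ConfigError("fit stage needs a tree and the primary climate proxy")
    tree = read_newick_file(cfg.tree, f=cfg.sampling_fraction)
    climate = read_series_csv(cfg.climate[cfg.primary_proxy])
    result = fit_candidate_models(
        tree,
        climate,
        n_starts=cfg.n_starts,
        seed=cfg.seed,
        grid_size=cfg.grid_size,
    )
    _write_json(out / "fits.json", result)
    return result


def stage_dcca(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.rtt is None or not cfg.climate:
        raise ConfigError("dcca stage needs an RTT ensemble and >= 1 proxy")
    ens = read_rtt_csv(cfg.rtt, burnin_frac=cfg.burnin_frac)
    if cfg.max_age is not None:
        ens = ens.restrict(cfg.max_age)
    results: dict = {"whole_tree": {}, "per_bioregion": {}}
    for proxy_name, path in sorted(cfg.climate.items()):
        proxy = read_series_csv(path, name=proxy_name)
        res = ensemble_climate_test(ens, proxy, box_size=cfg.box_size)
        results["whole_tree"][proxy_name] = res.to_dict()
    for region, path in sorted(cfg.region_rtt.items()):
        ens_r = read_rtt_csv(path, burnin_frac=cfg.burnin_frac)
        if cfg.max_age is not None:
            ens_r = ens_r.restrict(cfg.max_age)
        results["per_bioregion"][region] = {}
        for proxy_name, ppath in sorted(cfg.climate.items()):
            proxy = read_series_csv(ppath, name=proxy_name)
            res = ensemble_climate_test(ens_r, proxy, box_size=cfg.box_size)
            results["per_bioregion"][region][proxy_name] = res.to_dict()
    _write_json(out / "dcca.json", results)
    return results


def stage_tiptests(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.tree is None or cfg.tips is None:
        raise ConfigError("tiptests stage needs a tree and a tip table")
    tree = read_newick_file(cfg.tree, f=cfg.sampling_fraction)
    tips = TipTable.read_csv(cfg.tips).aligned_to(tree)
    results: dict = {}

    es = es_statistic(tree)
    results["es_summary"] = {
        "mean_ES": float(es["ES"].mean()),
        "mean_DR": float(es["DR"].mean()),
    }
    for col in ("latitude", "elevation_min", "elevation_max"):
        if col in tips.df.columns:
            trait = np.abs(tips.column(col).astype(float)) if col == "latitude" else tips.column(col).astype(float)
            results[f"essim_{col}"] = essim_test(
                tree, trait, n_sim=cfg.n_sim, seed=cfg.seed
            ).to_dict()
            results[f"strapp_{col}"] = strapp_test(
                tips, col, stat="spearman", n_perm=cfg.n_perm, seed=cfg.seed
            ).to_dict()

    if cfg.occurrences is not None:
        occ = pd.read_csv(cfg.occurrences)
        tropical, _ = classify_tropical(occ, mode="latitude")
        flag = tropical.reindex(tips.df.index).fillna(0).astype(int)
        tips2 = TipTable(tips.df.assign(tropical=flag.to_numpy()))
        if flag.nunique() == 2:
            results["strapp_tropical"] = strapp_test(
                tips2, "tropical", stat="mann_whitney",
                n_perm=cfg.n_perm, seed=cfg.seed,
            ).to_dict()
            results["d_statistic_tropical"] = d_statistic(
                tree, flag.to_numpy(), n_perm=max(cfg.n_perm, 100),
                n_sim=max(cfg.n_sim, 100), seed=cfg.seed,
            ).to_dict()

    if "bioregion" in tips.df.columns:
        results["strapp_bioregion"] = strapp_test(
            tips, "bioregion", stat="kruskal_wallis",
            n_perm=cfg.n_perm, seed=cfg.seed,
        ).to_dict()
    _write_json(out / "tiprate_tests.json", results)
    return results


def stage_bioregion(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.regions is None or cfg.tips is None:
        raise ConfigError("bioregion stage needs region and tip tables")
    assignment = read_region_table(cfg.regions)
    endemics = filter_endemics(assignment)
    results: dict = {
        "n_species": len(assignment),
        "n_endemic": len(endemics),
        "endemic_counts": {
            r: sum(1 for v in endemics.values() if v == r)
            for r in sorted(set(endemics.values()))
        },
    }

    tips_df = pd.read_csv(cfg.tips).set_index("species")
    if cfg.occurrences is not None:
        occ = pd.read_csv(cfg.occurrences)
        summaries, n_excluded = grid_summary(
            occ, tips_df["tip_rate"].to_dict(), cell_area_km2=cfg.cell_area_km2
        )
        grid_summary_frame(summaries).to_csv(out / "grid.csv", index=False)
        results["grid"] = {
            "n_cells": len(summaries),
            "n_records_excluded": n_excluded,
        }

    if cfg.region_rtt:
        curves = {}
        climate = (
            read_series_csv(cfg.climate[cfg.primary_proxy])
            if cfg.primary_proxy in cfg.climate
            else None
        )
        rate_temp = {}
        ages = None
        for region, path in sorted(cfg.region_rtt.items()):
            ens = read_rtt_csv(path, burnin_frac=cfg.burnin_frac)
            curves[region] = ens.mean_curve()
            ages = ens.ages
            if climate is not None:
                rate_temp[region] = fit_rate_temperature_curve(
                    ens.ages, ens.mean_curve(), climate, window=cfg.rate_temp_window
                )
        corr, flagged = region_rtt_correlations(curves)
        results["rtt_correlations"] = {
            "regions": list(corr.index),
            "matrix": [[None if np.isnan(v) else round(float(v), 6) for v in row]
                       for row in corr.to_numpy()],
            "undefined": flagged,
        }
        if rate_temp:
            results["rate_vs_temperature"] = rate_temp
    _write_json(out / "bioregion.json", results)
    return results


STAGES = {
    "fit": stage_fit,
    "dcca": stage_dcca,
    "tiptests": stage_tiptests,
    "bioregion": stage_bioregion,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for name in stages or list(STAGES):
        if name not in STAGES:
            raise ConfigError(f"unknown stage {name!r}")
        log.info("running stage %s", name)
        try:
            results[name] = STAGES[name](cfg, out)
        except (ConfigError, DataError) as exc:
            raise type(exc)(f"stage {name}: {exc}") from exc
    inputs = {}
    for label, path in [
        ("tree", cfg.tree),
        ("rtt", cfg.rtt),
        ("tips", cfg.tips),
        ("occurrences", cfg.occurrences),
        ("regions", cfg.regions),
        *((f"climate_{k}", v) for k, v in sorted(cfg.climate.items())),
        *((f"region_rtt_{k}", v) for k, v in sorted(cfg.region_rtt.items())),
    ]:
        if path is not None:
            inputs[label] = {"path": str(path), "sha256": _sha256(path)}
    _write_json(
        out / "manifest.json",
        {
            "package_version": __version__,
            "seed": cfg.seed,
            "inputs": inputs,
            "stages": sorted(results),
        },
    )
    return results
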
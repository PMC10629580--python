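import numpy as np
import pandas as pd
import pytest

import chronodiv as cd
from chronodiv.bioregions import (
    filter_endemics,
    grid_summary,
    region_rtt_correlations,
)
from chronodiv.errors import DataError


def test_filter_endemics_basics():
    out = filter_endemics({"sp1": {"Africa"}, "sp2": {"Africa", "Eurasia"}})
    assert out == {"sp1": "Africa"}
    with pytest.warns(UserWarning):
        assert filter_endemics({"sp": {"Africa", "Pacific"}}) == {}


def test_filter_endemics_matches_generator_bookkeeping():
    rng = np.random.default_rng(0)
    regions = ["Africa", "Eurasia", "Pacific"]
    assignment = {}
    n_endemic = 0
    for i in range(300):
        first = regions[rng.integers(3)]
        if rng.random() < 0.1:
            second = regions[rng.integers(3)]
            assignment[f"s{i}"] = {first, second}
            n_endemic += first == second
        else:
            assignment[f"s{i}"] = {first}
            n_endemic += 1
    assert len(filter_endemics(assignment)) == n_endemic


def test_grid_summary_small_cases():
    occ = pd.DataFrame(
        {"species": ["a", "b", "a"], "lon": [10.0, 10.0, 10.3], "lat": [5.0, 5.0, 5.0]}
    )
    cells, excluded = grid_summary(occ, {"a": 1.0, "b": 3.0}, cell_area_km2=200.0)
    assert excluded == 0
    by_id = {c.cell_id: c for c in cells}
    shared = [c for c in cells if c.richness == 2]
    assert len(shared) == 1
    assert shared[0].mean_rate == pytest.approx(2.0)  # unweighted mean of 1 and 3

    # species without a rate is excluded with a count
    cells, excluded = grid_summary(occ, {"a": 1.0}, cell_area_km2=200.0)
    assert excluded == 1
    assert all(c.mean_rate == 1.0 for c in cells)


def test_grid_summary_matches_recount():
    region_of = {f"s{i}": "Africa" for i in range(30)}
    occ = cd.simulate_occurrences(region_of, spread_deg=1.5, n_per_species=6, seed=2)
    rates = {sp: 0.1 + 0.01 * i for i, sp in enumerate(sorted(region_of))}
    cells, _ = grid_summary(occ, rates, cell_area_km2=200.0)
    # brute-force recount per reported cell
    side = np.sqrt(200.0) / 111.195
    for c in cells:
        ix, iy = (int(v) for v in c.cell_id.split("_"))
        inside = occ[
            (np.floor((occ["lon"] + 180.0) / side).astype(int) == ix)
            & (np.floor((occ["lat"] + 90.0) / side).astype(int) == iy)
        ]
        assert c.richness == inside["species"].nunique()
    # total per-cell richness >= number of distinct species observed
    assert sum(c.richness for c in cells) >= occ["species"].nunique()


def test_grid_summary_rejects_bad_coordinates():
    occ = pd.DataFrame({"species": ["a"], "lon": [200.0], "lat": [0.0]})
    with pytest.raises(DataError):
        grid_summary(occ, {"a": 1.0})


def test_region_rtt_correlations_structure():
    t = np.linspace(0, 1, 30)
    base = np.sin(2 * np.pi * t) + 2.0
    curves = {"Africa": base, "Eurasia": base.copy(), "Pacific": -base}
    corr, flagged = region_rtt_correlations(curves)
    assert flagged == []
    assert np.allclose(np.diag(corr.to_numpy()), 1.0)
    assert corr.loc["Africa", "Eurasia"] == pytest.approx(1.0)
    assert corr.loc["Africa", "Pacific"] == pytest.approx(-1.0)
    assert np.allclose(corr.to_numpy(), corr.to_numpy().T)

    # random curves equal direct pairwise recomputation; PSD up to tolerance
    rng = np.random.default_rng(1)
    curves = {f"r{i}": rng.normal(size=30) for i in range(5)}
    corr, _ = region_rtt_correlations(curves)
    names = sorted(curves)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            expected = np.corrcoef(curves[a], curves[b])[0, 1]
            assert corr.loc[a, b] == pytest.approx(expected, abs=1e-12)
    assert np.linalg.eigvalsh(corr.to_numpy()).min() > -1e-10


def test_region_rtt_constant_curve_flagged():
    curves = {"Africa": np.ones(10), "Eurasia": np.arange(10.0)}
    corr, flagged = region_rtt_correlations(curves)
    assert flagged == ["Africa"]
    assert np.isnan(corr.loc["Africa", "Eurasia"])
    assert corr.loc["Africa", "Africa"] == 1.0
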
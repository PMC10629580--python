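"""Bioregion-level summaries: endemic filtering, occurrence grid maps,
and cross-region rate-through-time correlations.

Regions follow the seven classic orchid bioregions (Africa, Australia,
Eurasia, North America, Neotropics, Pacific, Southeast Asia) but any
label set works; membership is an input table, not a GIS operation.
Grid cells are equal-angle lon/lat bins whose side is chosen so the cell
area at the equator matches a target (default 200 km^2) — a deliberately
simple geometry whose size is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

BIOREGIONS = (
    "Africa",
    "Australia",
    "Eurasia",
    "North America",
    "Neotropics",
    "Pacific",
    "Southeast Asia",
)

KM_PER_DEGREE = 111.195  # mean meridian arc length per degree


def read_region_table(path: str) -> dict[str, set[str]]:
    """CSV ``species,bioregion`` (repeat rows for multi-region species)
    -> species -> set of regions."""
    df = pd.read_csv(path)
    for col in ("species", "bioregion"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    out: dict[str, set[str]] = {}
    for sp, region in zip(df["species"], df["bioregion"]):
        out.setdefault(sp, set()).add(region)
    return out


def filter_endemics(assignment: dict[str, set[str]]) -> dict[str, str]:
    """Keep only species present in exactly one bioregion."""
    for sp, regions in assignment.items():
        if not regions:
            raise DataError(f"species {sp!r} has an empty region set")
    endemics = {sp: next(iter(r)) for sp, r in assignment.items() if len(r) == 1}
    if not endemics:
        warnings.warn("no endemic species remain after filtering", stacklevel=2)
    return endemics


@dataclass(frozen=True)
class GridSummary:
    cell_id: str
    lon: float
    lat: float
    richness: int
    mean_rate: float


def grid_summary(
    occurrences: pd.DataFrame,
    tip_rates: dict[str, float],
    cell_area_km2: float = 200.0,
) -> tuple[list[GridSummary], int]:
    """Species richness and mean tip rate per occupied grid cell.

    Richness counts distinct species per cell; the mean rate is the
    unweighted mean of the tip rates of those species.  Occurrences of
    species without a tip rate are excluded; the count of such records is
    returned alongside the summaries.
    """
    for col in ("species", "lon", "lat"):
        if col not in occurrences.columns:
            raise DataError(f"occurrence table needs column {col!r}")
    occ = occurrences.copy()
    if (
        occ["lon"].abs().max() > 180.0 + 1e-9
        or occ["lat"].abs().max() > 90.0 + 1e-9
    ):
        raise DataError("occurrences outside lon [-180,180] / lat [-90,90]")
    has_rate = occ["species"].isin(tip_rates)
    n_excluded = int((~has_rate).sum())
    occ = occ[has_rate]
    side_deg = math.sqrt(cell_area_km2) / KM_PER_DEGREE
    ix = np.floor((occ["lon"].to_numpy() + 180.0) / side_deg).astype(int)
    iy = np.floor((occ["lat"].to_numpy() + 90.0) / side_deg).astype(int)
    occ = occ.assign(_ix=ix, _iy=iy)
    summaries: list[GridSummary] = []
    for (cx, cy), group in occ.groupby(["_ix", "_iy"], sort=True):
        species = sorted(set(group["species"]))
        rates = [tip_rates[sp] for sp in species]
        summaries.append(
            GridSummary(
                cell_id=f"{cx}_{cy}",
                lon=round(-180.0 + (cx + 0.5) * side_deg, 6),
                lat=round(-90.0 + (cy + 0.5) * side_deg, 6),
                richness=len(species),
                mean_rate=float(np.mean(rates)),
            )
        )
    return summaries, n_excluded


def grid_summary_frame(summaries: list[GridSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "lon": s.lon,
                "lat": s.lat,
                "richness": s.richness,
                "mean_rate": s.mean_rate,
            }
            for s in summaries
        ]
    )


def region_rtt_correlations(
    region_curves: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlation matrix of per-region rate-through-time
    curves sharing one age grid.  Regions with a constant curve have an
    undefined correlation; their rows/columns are NaN (except the unit
    diagonal) and they are reported in the second return value.
    """
    regions = sorted(region_curves)
    if len(regions) < 2:
        raise DataError("need curves for at least 2 regions")
    lengths = {len(np.asarray(region_curves[r])) for r in regions}
    if len(lengths) != 1:
        raise DataError("region curves must share one age grid")
    mat = np.vstack([np.asarray(region_curves[r], dtype=float) for r in regions])
    flagged = [r for r, row in zip(regions, mat) if np.ptp(row) == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    for i, r in enumerate(regions):
        if r in flagged:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
        corr[i, i] = 1.0
    return pd.DataFrame(corr, index=regions, columns=regions), flagged
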
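"""Population-weighted exposure aggregation from gridded arrays.

A country's population-weighted PM2.5 is the population-weighted mean of
gridded concentration over the cells assigned to that country:
``pwPM2.5 = sum_i pm_i * pop_i / sum_i pop_i``.  Cells with an undefined
zone are ignored; cells with population but missing concentration are
excluded from numerator and denominator alike, and the per-zone coverage
fraction (share of zone population over cells with a defined
concentration) is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import COVARIATES, PanelData

__all__ = ["GridStack", "population_weighted_mean", "zonal_table", "attach_exposure"]


@dataclass(frozen=True)
class GridStack:
    """Aligned 2-D grids of pollutant concentration, population, and zone id.

    ``pm`` in ug/m3 (NaN allowed = missing); ``pop`` non-negative counts;
    ``zones`` zone id per cell with NaN marking cells outside any zone.
    """

    pm: np.ndarray
    pop: np.ndarray
    zones: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "pm", np.asarray(self.pm, dtype=float))
        object.__setattr__(self, "pop", np.asarray(self.pop, dtype=float))
        object.__setattr__(self, "zones", np.asarray(self.zones, dtype=float))
        if not (self.pm.shape == self.pop.shape == self.zones.shape):
            raise ValueError(
                f"grid shapes differ: pm {self.pm.shape}, pop {self.pop.shape}, "
                f"zones {self.zones.shape}"
            )
        if self.pm.ndim != 2:
            raise ValueError("grids must be 2-D")
        in_zone = np.isfinite(self.zones)
        pm_vals = self.pm[in_zone & np.isfinite(self.pm)]
        if np.any(pm_vals < 0):
            raise ValueError("pm must be non-negative where defined")
        if np.any(~np.isfinite(self.pop)) or np.any(self.pop < 0):
            raise ValueError("pop must be finite and non-negative everywhere")

    def zone_ids(self) -> np.ndarray:
        z = self.zones[np.isfinite(self.zones)]
        return np.unique(z)


def population_weighted_mean(grids: GridStack) -> dict:
    """Population-weighted mean concentration per zone.

    Returns a mapping zone id -> value.  A zone whose total population over
    concentration-covered cells is zero gets NaN and a warning (never a
    silent 0).  Accumulation is row-major in double precision.
    """
    table = zonal_table(grids)
    return dict(zip(table["zone_id"], table["pwpm25"]))


def zonal_table(grids: GridStack) -> pd.DataFrame:
    """Per-zone exposure with coverage diagnostics.

    Columns: ``zone_id``, ``pwpm25``, ``coverage_fraction`` (share of the
    zone's population in cells where pm is defined; 0 when the zone has no
    population at all).
    """
    zones = grids.zones.ravel()
    pm = grids.pm.ravel()
    pop = grids.pop.ravel()
    in_zone = np.isfinite(zones)
    zone_ids = np.unique(zones[in_zone])
    rows = []
    for zid in zone_ids:
        sel = in_zone & (zones == zid)
        covered = sel & np.isfinite(pm)
        pop_total = float(pop[sel].sum())
        pop_covered = float(pop[covered].sum())
        coverage = pop_covered / pop_total if pop_total > 0 else 0.0
        if pop_covered > 0:
            value = float((pm[covered] * pop[covered]).sum() / pop_covered)
        else:
            value = float("nan")
            warnings.warn(
                f"zone {zid:g}: zero population over concentration-covered "
                "cells; exposure set to missing",
                stacklevel=2,
            )
        rows.append({"zone_id": zid, "pwpm25": value, "coverage_fraction": coverage})
    return pd.DataFrame(rows, columns=["zone_id", "pwpm25", "coverage_fraction"])


def attach_exposure(panel: PanelData, exposures: dict) -> PanelData:
    """Attach per-(zone, year) exposure values to the panel's pwPM2.5 column.

    ``exposures`` maps ``(country_id, year)`` to a value.  Entries for
    countries absent from the panel are skipped with a warning; duplicate
    keys cannot occur in a dict but a list of (key, value) pairs with
    repeats is rejected.  Returns a new panel; unmatched cells stay as-is.
    """
    if not isinstance(exposures, dict):
        pairs = list(exposures)
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate (zone, year) key {dup!r} in exposures")
        exposures = dict(pairs)
    cindex = panel.country_index()
    yindex = panel.year_index()
    X = panel.X.copy()
    k_pm = COVARIATES.index("pwpm25")
    for (cid, year), value in exposures.items():
        if cid not in cindex:
            warnings.warn(
                f"exposure entry for {cid!r} skipped: not in panel", stacklevel=2
            )
            continue
        if int(year) not in yindex:
            warnings.warn(
                f"exposure entry for ({cid!r}, {year}) skipped: year not in panel",
                stacklevel=2,
            )
            continue
        X[cindex[cid], yindex[int(year)], k_pm] = value
    return PanelData(
        country_ids=panel.country_ids,
        years=panel.years,
        y=panel.y.copy(),
        X=X,
        region=panel.region.copy(),
        outcome=panel.outcome,
    )
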
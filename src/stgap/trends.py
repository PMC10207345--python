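"""Descriptive trend taxonomy and region-average series for panel outcomes.

Country trajectories of the gender gap are sorted into three classes: an
increase-then-decrease shape with an interior peak, a monotone increasing
trend, or a monotone decreasing trend.  The classification smooths the
series with a centered moving average, requires the smoothed maximum to
sit well inside the observation window with a material rise before it and
fall after it, and otherwise labels the country by the sign of the
Theil-Sen slope.  All three knobs (smoothing window, edge margin, minimum
rise/fall) are parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .panel import PanelData

__all__ = [
    "TrendClassification",
    "classify_trend",
    "classify_panel",
    "region_average",
    "peak_value_table",
]


@dataclass(frozen=True)
class TrendClassification:
    """Label plus peak location/value (present iff label == "peak")."""

    label: str                     # "peak" | "increasing" | "decreasing"
    peak_year: int | None
    peak_value: float | None
    slope_estimate: float          # Theil-Sen slope per decade

    def __post_init__(self):
        has_peak = self.peak_year is not None and self.peak_value is not None
        if (self.label == "peak") != has_peak:
            raise ValueError("peak_year/peak_value present iff label == 'peak'")


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaN; window truncated at the edges."""
    half = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        seg = values[max(0, i - half): min(n, i + half + 1)]
        seg = seg[np.isfinite(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


def classify_trend(
    series,
    years,
    window: int = 5,
    edge_margin: int = 3,
    epsilon: float = 0.25,
    min_obs: int = 7,
) -> TrendClassification:
    """Classify one per-year series as peaked, increasing, or decreasing.

    The series is smoothed with a centered moving average of the given
    window.  It is labeled "peak" when the smoothed argmax lies at least
    ``edge_margin`` years inside both ends and the smoothed rise
    (max - first) and fall (max - last) both reach ``epsilon``; the
    reported peak value is the raw series value at the smoothed argmax
    year.  Otherwise the label is the sign of the Theil-Sen slope.
    """
    series = np.asarray(series, dtype=float)
    years = np.asarray(years, dtype=int)
    if series.shape != years.shape:
        raise ValueError("series and years must have the same length")
    finite = np.isfinite(series)
    if finite.sum() < min_obs:
        raise ValueError(
            f"need at least {min_obs} non-missing observations, got {int(finite.sum())}"
        )
    slope = float(theilslopes(series[finite], years[finite]).slope) * 10.0

    smooth = _moving_average(series, window)
    ok = np.isfinite(smooth)
    idx_ok = np.flatnonzero(ok)
    k = idx_ok[np.argmax(smooth[idx_ok])]
    peak_year = int(years[k])
    interior = (
        peak_year - years[finite].min() >= edge_margin
        and years[finite].max() - peak_year >= edge_margin
    )
    first = smooth[idx_ok[0]]
    last = smooth[idx_ok[-1]]
    rise = smooth[k] - first
    fall = smooth[k] - last
    if interior and rise >= epsilon and fall >= epsilon:
        raw_at_peak = series[k]
        if not np.isfinite(raw_at_peak):  # fall back to the smoothed value
            raw_at_peak = smooth[k]
        return TrendClassification(
            label="peak",
            peak_year=peak_year,
            peak_value=float(raw_at_peak),
            slope_estimate=slope,
        )
    label = "increasing" if slope >= 0 else "decreasing"
    return TrendClassification(
        label=label, peak_year=None, peak_value=None, slope_estimate=slope
    )


def classify_panel(panel: PanelData, **kwargs) -> dict:
    """Classify every country with enough observations; returns id -> class."""
    out = {}
    for i, cid in enumerate(panel.country_ids):
        try:
            out[cid] = classify_trend(panel.y[i], panel.years, **kwargs)
        except ValueError:
            continue  # too few observations
    return out


def region_average(panel: PanelData, region_map: dict | None = None) -> pd.DataFrame:
    """Unweighted per-region per-year mean of the outcome.

    ``region_map`` (country -> region) defaults to the panel's own region
    labels; every panel country must be mapped.  Years where a country is
    missing are averaged over the remaining countries, and the number of
    contributing countries is reported.  Regions with no countries are
    omitted with a warning.
    """
    if region_map is None:
        region_map = dict(zip(panel.country_ids, panel.region))
    unmapped = [c for c in panel.country_ids if c not in region_map]
    if unmapped:
        raise ValueError(f"countries without a region: {unmapped[:5]}")
    regions = sorted({region_map[c] for c in panel.country_ids})
    rows = []
    for reg in regions:
        idx = [i for i, c in enumerate(panel.country_ids) if region_map[c] == reg]
        if not idx:
            warnings.warn(f"region {reg!r} has no countries; omitted", stacklevel=2)
            continue
        block = panel.y[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(block, axis=0)
        counts = np.isfinite(block).sum(axis=0)
        for j, yr in enumerate(panel.years):
            rows.append(
                {"region": reg, "year": int(yr),
                 "mean": means[j] if counts[j] else np.nan,
                 "n_countries": int(counts[j])}
            )
    return pd.DataFrame(rows)


def peak_value_table(classifications: dict) -> pd.DataFrame:
    """Countries with a peak, sorted by peak value descending."""
    rows = [
        {"country_id": cid, "peak_year": c.peak_year, "peak_value": c.peak_value}
        for cid, c in classifications.items()
        if c.label == "peak"
    ]
    df = pd.DataFrame(rows, columns=["country_id", "peak_year", "peak_value"])
    if len(df):
        df = df.sort_values("peak_value", ascending=False, kind="stable").reset_index(
            drop=True
        )
    return df
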
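"""Country-by-year panel container and CSV readers/writers.

The panel holds one outcome matrix (gender gap in life expectancy, or a
gender-specific life expectancy), six strictly positive covariates that
enter the regression on the natural-log scale, and a region label per
country.  Missing values are NaN; the lattice is always rectangular
(every country appears at every year, with explicit missing markers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "OUTCOMES",
    "PanelData",
    "read_panel_csv",
    "write_panel_csv",
    "read_regions_csv",
    "write_regions_csv",
]

#: covariate column order: population-weighted PM2.5 (ug/m3), urban
#: population share (%), poverty gap index, female share of primary
#: enrollment (%), caloric supply (kcal/capita/day), smoking death rate
#: (per 100,000)
COVARIATES = ("pwpm25", "urbanpop", "poverty", "education", "calories", "smoking")

OUTCOMES = ("ggle", "le_m", "le_f")


@dataclass
class PanelData:
    """Rectangular country x year panel.

    Attributes
    ----------
    country_ids : tuple of str
        Ordered country labels (rows of the matrices).
    years : ndarray of int
        Ordered years (columns).
    y : ndarray, shape (n, T)
        Outcome values; NaN marks missing.
    X : ndarray, shape (n, T, 6)
        Covariates in :data:`COVARIATES` order; NaN marks missing.
    region : ndarray of object, shape (n,)
        Region label per country (may be empty strings when unused).
    outcome : str
        Which outcome ``y`` holds ("ggle", "le_m", or "le_f").
    """

    country_ids: tuple
    years: np.ndarray
    y: np.ndarray
    X: np.ndarray
    region: np.ndarray = field(default=None)
    outcome: str = "ggle"

    def __post_init__(self):
        self.country_ids = tuple(self.country_ids)
        self.years = np.asarray(self.years, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, T = len(self.country_ids), len(self.years)
        if self.y.shape != (n, T):
            raise ValueError(f"y has shape {self.y.shape}, expected {(n, T)}")
        if self.X.shape != (n, T, len(COVARIATES)):
            raise ValueError(
                f"X has shape {self.X.shape}, expected {(n, T, len(COVARIATES))}"
            )
        if self.region is None:
            self.region = np.array([""] * n, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        if self.region.shape != (n,):
            raise ValueError("region must have one label per country")
        bad = np.isfinite(self.X) & (self.X <= 0)
        if bad.any():
            i, j, k = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"covariate {COVARIATES[k]!r} is {self.X[i, j, k]:g} for country "
                f"{self.country_ids[i]!r} in year {int(self.years[j])}; covariates "
                "must be strictly positive where observed (they enter on the log scale)"
            )

    @property
    def n_countries(self) -> int:
        return len(self.country_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def country_index(self) -> dict:
        return {c: i for i, c in enumerate(self.country_ids)}

    def year_index(self) -> dict:
        return {int(t): j for j, t in enumerate(self.years)}

    def region_labels(self) -> tuple:
        """Distinct region labels in first-appearance order."""
        seen = []
        for r in self.region:
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.country_ids):
            for j, yr in enumerate(self.years):
                row = {"country_id": cid, "year": int(yr), self.outcome: self.y[i, j]}
                for k, name in enumerate(COVARIATES):
                    row[name] = self.X[i, j, k]
                row["region"] = self.region[i]
                rows.append(row)
        return pd.DataFrame(rows)


def read_panel_csv(path, outcome: str = "ggle") -> PanelData:
    """Read a long-format panel CSV into a rectangular :class:`PanelData`.

    Required columns: ``country_id``, ``year``, and at least one of
    ``ggle``, ``le_m``, ``le_f``.  When ``ggle`` is requested but absent
    (or missing in some rows) and both life-expectancy columns are present,
    it is backfilled as ``le_f - le_m``.  Empty fields and ``NA`` are read
    as missing; duplicate (country, year) rows are an error.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, comment="#")
    if "country_id" not in df.columns or "year" not in df.columns:
        raise ValueError("panel CSV must have country_id and year columns")
    present_outcomes = [c for c in OUTCOMES if c in df.columns]
    if not present_outcomes:
        raise ValueError(f"panel CSV must have at least one of {OUTCOMES}")
    dup = df.duplicated(subset=["country_id", "year"])
    if dup.any():
        first = df.loc[dup, ["country_id", "year"]].iloc[0]
        raise ValueError(
            f"duplicate (country, year) row: ({first['country_id']}, {first['year']})"
        )
    numeric_cols = present_outcomes + [c for c in COVARIATES if c in df.columns]
    for col in numeric_cols + ["year"]:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            rownum = int(bad.index[0]) if len(bad) else -1
            raise ValueError(f"non-numeric value in column {col!r} (row {rownum})") from exc

    if outcome == "ggle" and {"le_f", "le_m"}.issubset(df.columns):
        if "ggle" not in df.columns:
            df["ggle"] = np.nan
        fill = df["ggle"].isna() & df["le_f"].notna() & df["le_m"].notna()
        df.loc[fill, "ggle"] = df.loc[fill, "le_f"] - df.loc[fill, "le_m"]
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} not present and not derivable")

    countries = tuple(sorted(df["country_id"].astype(str).unique()))
    years = np.array(sorted(df["year"].unique()), dtype=int)
    cindex = {c: i for i, c in enumerate(countries)}
    yindex = {int(t): j for j, t in enumerate(years)}
    n, T = len(countries), len(years)
    y = np.full((n, T), np.nan)
    X = np.full((n, T, len(COVARIATES)), np.nan)
    region = np.array([""] * n, dtype=object)
    has_region = "region" in df.columns
    for _, row in df.iterrows():
        i = cindex[str(row["country_id"])]
        j = yindex[int(row["year"])]
        y[i, j] = row[outcome]
        for k, name in enumerate(COVARIATES):
            if name in df.columns:
                X[i, j, k] = row[name]
        if has_region and isinstance(row["region"], str):
            region[i] = row["region"]
    return PanelData(
        country_ids=countries, years=years, y=y, X=X, region=region, outcome=outcome
    )


def write_panel_csv(panel: PanelData, path, header_lines=()) -> None:
    """Write a panel as long-format CSV (countries and years in sorted order).

    Missing values are written as empty fields.
    """
    df = panel.to_dataframe()
    order = np.lexsort((df["year"].to_numpy(), df["country_id"].to_numpy()))
    df = df.iloc[order]
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, na_rep="", lineterminator="\n")


def read_regions_csv(path) -> dict:
    """Read a (country_id, region) CSV into a mapping."""
    df = pd.read_csv(path, comment="#")
    if "country_id" not in df.columns or "region" not in df.columns:
        raise ValueError("regions CSV must have country_id and region columns")
    return dict(zip(df["country_id"].astype(str), df["region"].astype(str)))


def write_regions_csv(panel: PanelData, path, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("country_id,region\n")
        for cid, reg in sorted(zip(panel.country_ids, panel.region)):
            fh.write(f"{cid},{reg}\n")
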
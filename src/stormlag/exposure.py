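"""Beaufort-threshold classification of county-day peak sustained winds.

A county-day is a tropical-cyclone exposure day when its peak sustained
wind at the county population mean center reaches gale force (>=34 kt);
exposures at or above 64 kt are hurricane force.  The module also builds
exposure panels on a full county-day grid and computes descriptive
summaries (per-month, per-state, per-county counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UNEXPOSED",
    "GALE",
    "HURRICANE",
    "GALE_KNOTS",
    "HURRICANE_KNOTS",
    "classify_wind",
    "make_exposure_panel",
    "summarize_exposure",
    "read_wind_table",
    "ExposureSummary",
]

UNEXPOSED = "unexposed"
GALE = "gale_to_violent_storm"
HURRICANE = "hurricane"

#: gale force on the Beaufort scale, knots (inclusive threshold)
GALE_KNOTS = 34.0
#: hurricane force on the Beaufort scale, knots (inclusive threshold)
HURRICANE_KNOTS = 64.0

KNOT_PER_MPS = 1.0 / 0.514444


def classify_wind(wind_knots):
    """Map peak sustained wind (knots) to an exposure category.

    <34 kt is unexposed, [34, 64) kt is gale- to violent-storm force,
    >=64 kt is hurricane force.  Thresholds are inclusive ("reached or
    exceeded") and winds are compared unrounded.  Accepts scalars or
    arrays; raises on negative or non-finite winds.
    """
    w = np.asarray(wind_knots, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("wind_knots must be non-negative and finite")
    out = np.select([w >= HURRICANE_KNOTS, w >= GALE_KNOTS], [HURRICANE, GALE], UNEXPOSED)
    if np.isscalar(wind_knots) or np.ndim(wind_knots) == 0:
        return str(out)
    return out


def make_exposure_panel(
    wind_records: pd.DataFrame, grid: pd.DataFrame
) -> pd.DataFrame:
    """Classify every county-day in ``grid`` from wind records.

    ``wind_records`` has columns (county_id, date, wind_knots); ``grid``
    has (county_id, date) covering the study panel.  County-days without
    a wind record are unexposed; duplicate county-day records (several
    storms) are resolved by the maximum wind.  Records outside the grid
    raise.
    """
    grid = grid[["county_id", "date"]].drop_duplicates().copy()
    if len(wind_records):
        rec = (
            wind_records.groupby(["county_id", "date"], as_index=False)["wind_knots"]
            .max()
        )
        merged = grid.merge(rec, on=["county_id", "date"], how="outer", indicator=True)
        if (merged["_merge"] == "right_only").any():
            bad = merged.loc[merged["_merge"] == "right_only", ["county_id", "date"]]
            raise ValueError(
                f"{len(bad)} wind record(s) fall outside the county-day grid"
            )
        merged = merged.drop(columns="_merge")
    else:
        merged = grid.assign(wind_knots=np.nan)
    wind = merged["wind_knots"].fillna(0.0).to_numpy()
    merged["category"] = classify_wind(wind)
    merged["binary_exposed"] = merged["category"] != UNEXPOSED
    return merged[["county_id", "date", "category", "binary_exposed"]]


@dataclass
class ExposureSummary:
    """Descriptive summary of an exposure panel."""

    total_days: int
    n_exposed_counties: int
    per_month: pd.Series
    per_state: pd.Series
    per_county: pd.Series
    county_min: float
    county_median: float
    county_mean: float
    county_max: float
    hurricane_days: int
    hurricane_share: float

    @property
    def september_share(self) -> float:
        """Share of exposure days falling in September."""
        return float(self.per_month.get(9, 0)) / self.total_days


def summarize_exposure(
    exposure: pd.DataFrame, county_state_map: pd.Series | dict | None = None
) -> ExposureSummary:
    """Summarize exposure days by month, state, and county.

    ``county_state_map`` maps county id to state; when omitted, the state
    is the leading two characters of the FIPS-style county id.  Counties
    missing from an explicit map raise.
    """
    exp = exposure[exposure["category"] != UNEXPOSED]
    if exp.empty:
        raise ValueError("exposure panel contains no exposed county-days")
    dates = pd.to_datetime(exp["date"])
    per_month = exp.groupby(dates.dt.month).size()
    per_county = exp.groupby("county_id").size().sort_index()
    if county_state_map is None:
        states = exp["county_id"].str[:2]
    else:
        mapping = pd.Series(county_state_map)
        missing = set(exp["county_id"]) - set(mapping.index)
        if missing:
            raise KeyError(f"counties missing from state map: {sorted(missing)[:5]}")
        states = exp["county_id"].map(mapping)
    per_state = exp.groupby(states.rename("state")).size()
    hurr = int((exp["category"] == HURRICANE).sum())
    total = int(len(exp))
    return ExposureSummary(
        total_days=total,
        n_exposed_counties=int(per_county.size),
        per_month=per_month,
        per_state=per_state,
        per_county=per_county,
        county_min=float(per_county.min()),
        county_median=float(per_county.median()),
        county_mean=float(per_county.mean()),
        county_max=float(per_county.max()),
        hurricane_days=hurr,
        hurricane_share=hurr / total,
    )


def read_wind_table(path, units: str = "knots") -> pd.DataFrame:
    """Read a delimited wind table with columns (fips, date, vmax_sust).

    ``units`` selects the stored unit of ``vmax_sust``: ``"knots"`` or
    ``"mps"`` (converted at 1 kt = 0.514444 m/s before thresholding).
    """
    if units not in {"knots", "mps"}:
        raise ValueError("units must be 'knots' or 'mps'")
    tab = pd.read_csv(path, dtype={"fips": str})
    wind = tab["vmax_sust"].astype(float)
    if units == "mps":
        wind = wind * KNOT_PER_MPS
    return pd.DataFrame(
        {
            "county_id": tab["fips"].str.zfill(5),
            "date": pd.to_datetime(tab["date"]),
            "wind_knots": wind,
        }
    )
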
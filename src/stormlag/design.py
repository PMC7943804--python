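"""Design assembly for the matched-stratum distributed-lag model.

Builds everything to the right of the stratum intercepts: unconstrained
distributed-lag exposure indicators (lags 0..7), a linear temperature
term (lag 0 only, lags 0..7, or none), six day-of-week indicators with
Sunday as reference, a natural cubic spline in calendar year with two
degrees of freedom for long-term trends, and the log-population offset.
Rows are grouped into strata matched on county and calendar (month,
day); strata whose counts are all zero contribute nothing to the
conditional likelihood and are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import GALE, HURRICANE, UNEXPOSED

__all__ = [
    "DesignOptions",
    "AssembledDesign",
    "assign_strata",
    "build_lag_matrix",
    "natural_spline_basis",
    "build_design",
]


def assign_strata(county_id: str, date) -> tuple[str, int, int]:
    """Stratum key: (county, month, day-of-month).

    Keying on the calendar (month, day) rather than ordinal day-of-year
    keeps e.g. Sep-15 matched with Sep-15 across leap and non-leap
    years; Feb 29 forms its own sparse stratum of leap-year days.
    """
    d = pd.Timestamp(date)
    return (str(county_id), int(d.month), int(d.day))


def build_lag_matrix(
    exposed: pd.DataFrame, max_lag: int = 7, value_col: str = "exposed"
) -> pd.DataFrame:
    """Lagged exposure indicators on a contiguous daily grid.

    ``exposed`` has columns (county_id, date, <value_col>) with one row
    per county-day on a contiguous grid.  Column ``lag{l}`` at day t is
    the exposure status at day t - l within the same county; days whose
    lag-l antecedent precedes the grid take 0 (exposures are rare, so
    treating the pre-study week as unexposed is preferred to dropping
    the first rows).
    """
    df = exposed.sort_values(["county_id", "date"]).reset_index(drop=True)
    gaps = df.groupby("county_id")["date"].diff().dropna()
    if len(gaps) and not (gaps == pd.Timedelta(days=1)).all():
        raise ValueError("exposure series must lie on a contiguous daily grid")
    base = df[value_col].astype(float)
    out = pd.DataFrame(index=df.index)
    grp = base.groupby(df["county_id"].to_numpy())
    for l in range(max_lag + 1):
        out[f"lag{l}"] = grp.shift(l).fillna(0.0).to_numpy()
    out.insert(0, "date", df["date"].to_numpy())
    out.insert(0, "county_id", df["county_id"].to_numpy())
    return out


def natural_spline_basis(
    x, df: int = 2, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural (restricted) cubic spline basis without intercept.

    Returns ``df`` columns evaluated at ``x`` plus the knot vector.
    Boundary knots sit at min(x) and max(x) and the ``df - 1`` internal
    knots at equally spaced quantiles (``df = 2`` puts one knot at the
    median).  The basis is the truncated-power construction

        N_1(x) = x,   N_{k+1}(x) = d_k(x) - d_{K-1}(x),  k = 1..K-2,

    with ``d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k)``,
    which is cubic between knots and linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if knots is None:
        uniq = np.unique(x)
        n_knots = df + 1
        if uniq.size < n_knots:
            raise ValueError(
                f"need at least {n_knots} distinct values for df={df}"
            )
        probs = np.linspace(0.0, 1.0, n_knots)
        knots = np.quantile(uniq, probs)
    else:
        knots = np.asarray(knots, dtype=float)
    if df == 1:
        return x[:, None].copy(), knots
    K = knots.size
    xiK, xiK1 = knots[-1], knots[-2]

    def d(k: int) -> np.ndarray:
        return (
            np.clip(x - knots[k], 0.0, None) ** 3
            - np.clip(x - xiK, 0.0, None) ** 3
        ) / (xiK - knots[k])

    dK1 = (np.clip(x - xiK1, 0.0, None) ** 3 - np.clip(x - xiK, 0.0, None) ** 3) / (
        xiK - xiK1
    )
    cols = [x] + [d(k) - dK1 for k in range(K - 2)]
    return np.column_stack(cols), knots


@dataclass(frozen=True)
class DesignOptions:
    """Analysis-variant switches for design assembly.

    ``exposure_mode``: ``"binary"`` (one 8-lag block, any exposure) or
    ``"three_category"`` (separate 8-lag blocks for gale- and
    hurricane-force days, unexposed as reference).
    ``temperature_mode``: ``"lag0"``, ``"lags0_7"``, or ``"none"``.
    ``spline_on``: ``"year"`` (integer calendar year, the default) or
    ``"decimal_date"``.
    """

    exposure_mode: str = "binary"
    temperature_mode: str = "lag0"
    max_lag: int = 7
    spline_df: int = 2
    spline_on: str = "year"

    def __post_init__(self) -> None:
        if self.exposure_mode not in {"binary", "three_category"}:
            raise ValueError("exposure_mode must be 'binary' or 'three_category'")
        if self.temperature_mode not in {"lag0", "lags0_7", "none"}:
            raise ValueError("temperature_mode must be 'lag0', 'lags0_7' or 'none'")
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")


@dataclass
class AssembledDesign:
    """Model-ready arrays for the conditional quasi-Poisson fit."""

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    offset: np.ndarray
    stratum: np.ndarray
    stratum_labels: pd.Index
    n_strata_dropped: int
    rows: pd.DataFrame = field(repr=False)

    def frame(self) -> pd.DataFrame:
        """Covariates as a DataFrame (column registry applied)."""
        return pd.DataFrame(self.X, columns=self.columns)

    def to_csv(self, path, registry_path=None) -> None:
        out = self.rows[["county_id", "date"]].copy()
        out["y"] = self.y
        out["offset"] = self.offset
        out["stratum"] = self.stratum
        for j, name in enumerate(self.columns):
            out[name] = self.X[:, j]
        out.to_csv(path, index=False, float_format="%.12g")
        if registry_path is not None:
            with open(registry_path, "w") as fh:
                fh.write("\n".join(self.columns) + "\n")


_DOW_NAMES = ["mon", "tue", "wed", "thu", "fri", "sat"]  # Sunday = reference


def build_design(
    panel: pd.DataFrame,
    exposure: pd.DataFrame,
    options: DesignOptions = DesignOptions(),
) -> AssembledDesign:
    """Assemble the distributed-lag design from a panel and exposure grid.

    ``panel`` holds (county_id, date, count, population, temperature);
    ``exposure`` holds (county_id, date, category) on the same grid.
    Strata with zero total count are removed (their conditional
    likelihood contribution is identically zero); the count is recorded
    in ``n_strata_dropped``.
    """
    df = panel.sort_values(["county_id", "date"]).reset_index(drop=True)
    exp = exposure[["county_id", "date", "category"]]
    merged = df.merge(exp, on=["county_id", "date"], how="left", indicator=True)
    if (merged["_merge"] == "left_only").any():
        missing = merged.loc[merged["_merge"] == "left_only", "county_id"].unique()
        raise ValueError(
            f"panel county-days missing from exposure grid (e.g. {missing[:3]})"
        )
    merged = merged.drop(columns="_merge")

    blocks: list[tuple[str, pd.DataFrame]] = []
    if options.exposure_mode == "binary":
        merged["exposed"] = (merged["category"] != UNEXPOSED).astype(float)
        blocks.append(("exposure", merged))
    else:
        for name, cat in (("gale", GALE), ("hurricane", HURRICANE)):
            tmp = merged.copy()
            tmp["exposed"] = (tmp["category"] == cat).astype(float)
            blocks.append((name, tmp))

    cols: list[np.ndarray] = []
    names: list[str] = []
    for prefix, block in blocks:
        lags = build_lag_matrix(block, options.max_lag)
        for l in range(options.max_lag + 1):
            cols.append(lags[f"lag{l}"].to_numpy())
            names.append(f"{prefix}_lag{l}")

    if options.temperature_mode != "none":
        n_temp_lags = options.max_lag if options.temperature_mode == "lags0_7" else 0
        tlags = build_lag_matrix(
            merged.rename(columns={"temperature": "tval"}),
            n_temp_lags,
            value_col="tval",
        )
        for l in range(n_temp_lags + 1):
            cols.append(tlags[f"lag{l}"].to_numpy())
            names.append(f"temp_lag{l}")

    dates = pd.to_datetime(merged["date"])
    dow = dates.dt.dayofweek.to_numpy()
    for d, name in enumerate(_DOW_NAMES):
        cols.append((dow == d).astype(float))
        names.append(f"dow_{name}")

    if options.spline_on == "year":
        xval = dates.dt.year.to_numpy(dtype=float)
    else:
        xval = dates.dt.year.to_numpy(dtype=float) + (
            dates.dt.dayofyear.to_numpy(dtype=float) - 0.5
        ) / 365.25
    basis, _ = natural_spline_basis(xval, df=options.spline_df)
    for j in range(basis.shape[1]):
        cols.append(basis[:, j])
        names.append(f"year_spline_{j + 1}")

    if len(set(names)) != len(names):
        raise ValueError("duplicate design column names")

    X = np.column_stack(cols)
    y = merged["count"].to_numpy(dtype=float)
    if np.any(merged["population"].to_numpy() <= 0):
        raise ValueError("population must be positive")
    offset = np.log(merged["population"].to_numpy(dtype=float))

    key = pd.MultiIndex.from_arrays(
        [merged["county_id"], dates.dt.month, dates.dt.day],
        names=["county_id", "month", "day"],
    )
    codes, labels = pd.factorize(key, sort=True)
    totals = np.bincount(codes, weights=y, minlength=len(labels))
    keep_stratum = totals > 0
    keep = keep_stratum[codes]
    n_dropped = int((~keep_stratum).sum())

    codes_kept, labels_kept = pd.factorize(
        pd.Index(labels[codes[keep]]), sort=True
    )
    if np.any(~np.isfinite(X[keep])) or np.any(~np.isfinite(offset[keep])):
        raise ValueError("design contains non-finite values")
    return AssembledDesign(
        y=y[keep],
        X=X[keep],
        columns=names,
        offset=offset[keep],
        stratum=codes_kept,
        stratum_labels=labels_kept,
        n_strata_dropped=n_dropped,
        rows=merged.loc[keep, ["county_id", "date", "category"]].reset_index(
            drop=True
        ),
    )
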
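"""Deseasonalized anomalies, limitation-term anomalies, Ekman velocity, dominance.

The anomaly machinery works on monthly series: a monthly climatology (mean per
calendar month over a baseline of at least two full years), absolute and
percent deviations from it, and an optional centered rolling mean. Nutrient
limitation anomalies first map concentrations through the diatom Monod term and
then deseasonalize the transformed series. Ekman vertical velocity is the curl
of wind stress over (rho0 f), evaluated with centered differences on the
sphere and masked near the equator where f vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .config import EARTH_RADIUS, EQUATOR_MASK_LAT, OMEGA, RHO0
from .dynamics import PFTParams, Trajectory, biomass_fractions, monod

MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


# ---------------------------------------------------------------------------
# Monthly climatology and anomalies
# ---------------------------------------------------------------------------


@dataclass
class MonthlyClimatology:
    """Mean per calendar month over a baseline span."""

    variable: str
    values: np.ndarray  # 12 calendar-month means, Jan..Dec
    baseline: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise ValueError("a monthly climatology holds exactly 12 values")

    def __getitem__(self, month: int) -> float:
        return float(self.values[month - 1])


@dataclass
class AnomalySeries:
    """Absolute and percent deviations from a monthly climatology.

    Percent anomalies are relative to the climatological mean of the same
    calendar month and undefined (NaN) where that mean is zero.
    """

    time: pd.DatetimeIndex
    absolute: pd.Series
    percent: pd.Series
    variable: str = ""
    smoothed: bool = False
    window_months: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "absolute": self.absolute,
                "percent": self.percent,
                "smoothed": self.smoothed,
            },
            index=pd.Index(self.time, name="time"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def to_monthly(series: pd.Series) -> pd.Series:
    """Average a finer-resolution series to calendar months (month-start stamps)."""
    return series.resample("MS").mean()


def monthly_climatology(series: pd.Series,
                        baseline: tuple | None = None,
                        variable: str = "") -> MonthlyClimatology:
    """Mean per calendar month over the baseline span (missing values skipped).

    The baseline must span at least two full years and every calendar month
    must have at least one datum.
    """
    series = series.sort_index()
    if baseline is None:
        baseline = (series.index[0], series.index[-1])
    start, end = pd.Timestamp(baseline[0]), pd.Timestamp(baseline[1])
    if end - start < pd.Timedelta(days=2 * 365 - 31):
        raise ValueError("climatology baseline must cover at least two full years")
    sub = series.loc[start:end]
    means = sub.groupby(sub.index.month).mean()
    missing = [m for m in range(1, 13) if m not in means.index or
               np.isnan(means.loc[m])]
    if missing:
        raise ValueError(
            "no data in baseline for calendar month(s): "
            + ", ".join(MONTH_NAMES[m - 1] for m in missing)
        )
    return MonthlyClimatology(
        variable=variable or str(series.name or ""),
        values=means.reindex(range(1, 13)).to_numpy(),
        baseline=(start, end),
    )


def anomaly(series: pd.Series, clim: MonthlyClimatology) -> AnomalySeries:
    """Deviation of each monthly value from its calendar-month climatology."""
    months = series.index.month.to_numpy()
    ref = clim.values[months - 1]
    absolute = series - ref
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(ref != 0, 100.0 * absolute.to_numpy() / ref, np.nan)
    return AnomalySeries(
        time=pd.DatetimeIndex(series.index),
        absolute=absolute,
        percent=pd.Series(pct, index=series.index),
        variable=clim.variable,
    )


def rolling_mean(series: pd.Series, window_months: int = 6,
                 center: bool = True) -> pd.Series:
    """Missing-aware moving average with shrinking windows at the edges."""
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    return series.rolling(window_months, center=center, min_periods=1).mean()


def smooth_anomaly(anom: AnomalySeries, window_months: int = 6,
                   center: bool = True) -> AnomalySeries:
    return AnomalySeries(
        time=anom.time,
        absolute=rolling_mean(anom.absolute, window_months, center),
        percent=rolling_mean(anom.percent, window_months, center),
        variable=anom.variable,
        smoothed=True,
        window_months=window_months,
    )


def limitation_anomaly(nutrient_series: pd.Series, nutrient: str,
                       diatom_params: PFTParams,
                       baseline: tuple | None = None) -> AnomalySeries:
    """Anomaly of the growth-limiting Monod term for one nutrient.

    Concentrations are first transformed through the Monod function with the
    diatom half-saturation for that nutrient, then deseasonalized (transform
    first, anomaly second). Valid nutrient labels: nitrate, silicate, iron.
    """
    ks = {
        "nitrate": diatom_params.k_no3,
        "silicate": diatom_params.k_si,
        "iron": diatom_params.k_fe,
    }
    if nutrient not in ks:
        raise ValueError(
            f"unknown nutrient {nutrient!r}; valid: {sorted(ks)}"
        )
    transformed = pd.Series(
        monod(nutrient_series.to_numpy(), ks[nutrient]),
        index=nutrient_series.index,
        name=f"f_{nutrient}",
    )
    clim = monthly_climatology(transformed, baseline,
                               variable=f"limitation_{nutrient}")
    return anomaly(transformed, clim)


# ---------------------------------------------------------------------------
# Ekman vertical velocity
# ---------------------------------------------------------------------------


def ekman_vertical_velocity(wind: xr.Dataset, rho0: float = RHO0,
                            mask_lat: float = EQUATOR_MASK_LAT,
                            ) -> xr.DataArray:
    """Ekman pumping velocity w_E = curl(tau / (rho0 f)), in cm d^-1.

    Centered differences on the sphere (second order in the interior;
    second-order one-sided at the grid edges); positive upward. Masked (NaN)
    where |lat| < mask_lat because the Coriolis parameter vanishes.
    """
    lat = np.deg2rad(wind.lat.values)
    lon = np.deg2rad(wind.lon.values)
    if lat.size < 3 or lon.size < 3:
        raise ValueError("grid too small for centered differences (need >= 3 points)")
    f = 2 * OMEGA * np.sin(lat)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = wind.tau_y.values / (rho0 * f)
        gy = wind.tau_x.values / (rho0 * f)
        # d/dx = (1 / (R cos lat)) d/dlon ; d/dy = (1/R) d/dlat
        ddx = np.gradient(gx, lon, axis=1, edge_order=2) / (
            EARTH_RADIUS * np.cos(lat)[:, None]
        )
        ddy = np.gradient(gy, lat, axis=0, edge_order=2) / EARTH_RADIUS
    w = (ddx - ddy) * 8.64e6  # m s^-1 -> cm d^-1
    w[np.abs(wind.lat.values) < mask_lat, :] = np.nan
    return xr.DataArray(
        w, coords={"lat": wind.lat, "lon": wind.lon}, dims=("lat", "lon"),
        name="w_ekman", attrs={"units": "cm d-1", "positive": "up"},
    )


# ---------------------------------------------------------------------------
# Dominance classification
# ---------------------------------------------------------------------------


@dataclass
class DominanceRecord:
    time: pd.Timestamp
    chl_anomaly: float  # mg m^-3
    sst_anomaly: float  # degC
    dominant: str


def dominance(traj_or_fractions, sst_anom: AnomalySeries,
              chl_anom: AnomalySeries) -> pd.DataFrame:
    """Dominant PFT (largest biomass fraction) joined with SST/Chl anomalies.

    All three inputs must share the same time axis. Exact ties go to the
    lexicographically first PFT name. Returns a frame with columns
    ``dominant``, ``sst_anomaly``, ``chl_anomaly``.
    """
    if isinstance(traj_or_fractions, Trajectory):
        frac = biomass_fractions(traj_or_fractions)
    else:
        frac = traj_or_fractions
    t = pd.DatetimeIndex(frac.index)
    if not (t.equals(pd.DatetimeIndex(sst_anom.time))
            and t.equals(pd.DatetimeIndex(chl_anom.time))):
        raise ValueError("fraction and anomaly series must share one time axis")
    ordered = frac[sorted(frac.columns)]
    dominant = ordered.idxmax(axis=1)  # first max in sorted column order
    return pd.DataFrame(
        {
            "dominant": dominant,
            "sst_anomaly": sst_anom.absolute.to_numpy(),
            "chl_anomaly": chl_anom.absolute.to_numpy(),
        },
        index=pd.Index(t, name="time"),
    )
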
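"""Migration phenology from daily displacement series.

The classifier is the absolute-displacement method with a spatial gate: a
UTC+9 calendar day is an *active migration day* when the bird covered more
than 60 km (sum of consecutive-fix great-circle steps, each step assigned
to the date its start fix falls on) while located, by the spherical mean of
that day's fixes, between the northern limit of the wintering range
(40.9 deg N) and the southern limit of the breeding sites (64.9 deg N).

A *migratory window* (individual or population) spans the first to the
last active day of a season; its duration is the inclusive day count.
Active days before the summer band (7 Jun) belong to spring, after it
(31 Aug) to autumn.  Days with a single fix have no step and hence zero
distance; days without fixes are absent from the series, and the
gap-corrected activity proportion divides by days-with-data instead of the
full window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geodesy, seasons
from .track_store import Track

ACTIVE_DAY_KM = 60.0
WINTER_RANGE_NORTH_LAT = 40.9
BREEDING_RANGE_SOUTH_LAT = 64.9


def daily_series(track: Track) -> pd.DataFrame:
    """Per UTC+9 date: summed step distance, spherical-mean latitude, fix count."""
    f = track.fixes
    if len(f) == 0:
        return pd.DataFrame(columns=["bird_id", "date", "distance_km", "mean_lat", "n_fixes"])
    dates = seasons.to_local_dates(f["timestamp"])
    lat, lon = f["lat"].to_numpy(), f["lon"].to_numpy()
    step_km = geodesy.great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) if len(f) > 1 else np.array([])
    step_df = pd.DataFrame({"date": dates[:-1], "distance_km": step_km})
    dist = step_df.groupby("date")["distance_km"].sum()

    v = geodesy._to_unit_vectors(lat, lon)
    vdf = pd.DataFrame({"date": dates, "x": v[:, 0], "y": v[:, 1], "z": v[:, 2]})
    g = vdf.groupby("date")[["x", "y", "z"]].mean()
    mean_lat = np.degrees(np.arctan2(g["z"], np.hypot(g["x"], g["y"])))
    n_fixes = vdf.groupby("date").size()

    out = pd.DataFrame(
        {
            "bird_id": track.bird_id,
            "date": g.index,
            "distance_km": dist.reindex(g.index, fill_value=0.0).to_numpy(),
            "mean_lat": mean_lat.to_numpy(),
            "n_fixes": n_fixes.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def classify_active_days(
    days: pd.DataFrame,
    distance_threshold_km: float = ACTIVE_DAY_KM,
    lat_band: tuple[float, float] = (WINTER_RANGE_NORTH_LAT, BREEDING_RANGE_SOUTH_LAT),
) -> pd.DataFrame:
    """Add active (strict >60 km inside the latitude band) and season columns."""
    days = days.copy()
    lo, hi = lat_band
    days["in_band"] = (days["mean_lat"] >= lo) & (days["mean_lat"] <= hi)
    days["active"] = days["in_band"] & (days["distance_km"] > distance_threshold_km)
    days["season"] = seasons.assign_season(days["date"])
    days["migration_season"] = seasons.migration_season(days["date"])
    return days


@dataclass
class MigrationWindow:
    scope: str                      # individual | population
    season: str                     # spring | autumn
    year: int
    bird_id: str | None
    first_active: pd.Timestamp
    last_active: pd.Timestamp
    n_active_days: int
    n_days_with_data: int

    @property
    def duration_days(self) -> int:
        return int((self.last_active - self.first_active).days) + 1

    @property
    def prop_active(self) -> float:
        return self.n_active_days / self.duration_days

    @property
    def prop_active_corrected(self) -> float:
        """Activity proportion over days with data (gap-corrected)."""
        return self.n_active_days / self.n_days_with_data


def _window_from_group(g: pd.DataFrame, scope: str, season: str, year: int,
                       bird_id: str | None, all_days: pd.DataFrame) -> MigrationWindow:
    first, last = g["date"].min(), g["date"].max()
    in_win = all_days[(all_days["date"] >= first) & (all_days["date"] <= last)]
    if bird_id is not None:
        in_win = in_win[in_win["bird_id"] == bird_id]
    return MigrationWindow(
        scope=scope, season=season, year=year, bird_id=bird_id,
        first_active=first, last_active=last,
        n_active_days=int(g["active"].sum()),
        n_days_with_data=int(in_win["date"].nunique()),
    )


def individual_windows(days: pd.DataFrame) -> list[MigrationWindow]:
    """Per bird x migration season x calendar year windows over active days."""
    act = days[days["active"] & days["migration_season"].notna()]
    out = []
    for (bird, season, year), g in act.groupby(
        ["bird_id", "migration_season", act["date"].dt.year], sort=True
    ):
        out.append(_window_from_group(g, "individual", season, int(year), bird, days))
    return out


def population_window(days: pd.DataFrame, season: str, year: int) -> MigrationWindow | None:
    """All-birds-combined window for one migration season and year."""
    act = days[
        days["active"]
        & (days["migration_season"] == season)
        & (days["date"].dt.year == year)
    ]
    if len(act) == 0:
        return None
    return _window_from_group(act, "population", season, year, None, days)


def prop_active_in_window(days: pd.DataFrame, window: MigrationWindow, bird_id: str) -> dict:
    """One bird's activity proportions inside a (population) window."""
    sel = days[
        (days["bird_id"] == bird_id)
        & (days["date"] >= window.first_active)
        & (days["date"] <= window.last_active)
    ]
    n_active = int(sel["active"].sum())
    n_data = int(sel["date"].nunique())
    return {
        "bird_id": bird_id,
        "season": window.season,
        "year": window.year,
        "n_active_days": n_active,
        "prop_active": n_active / window.duration_days,
        "prop_active_corrected": n_active / n_data if n_data else float("nan"),
    }


def route_fraction_on_active_days(days: pd.DataFrame, window: MigrationWindow) -> float:
    """Share of the window's distance covered on active days, in [0, 1].

    NaN (flagged undefined) when no distance was covered in the window.
    """
    sel = days[(days["date"] >= window.first_active) & (days["date"] <= window.last_active)]
    if window.bird_id is not None:
        sel = sel[sel["bird_id"] == window.bird_id]
    total = sel["distance_km"].sum()
    if total <= 0:
        return float("nan")
    return float(sel.loc[sel["active"], "distance_km"].sum() / total)


def summering_class(track: Track, breeding_lat: float = BREEDING_RANGE_SOUTH_LAT,
                    outside_lat: float = 60.0) -> str:
    """Whether the bird summered within the breeding range.

    "within" if any summer-band fix reaches ``breeding_lat``; "outside" if
    all summer fixes stay below ``outside_lat``; "mixed" otherwise (fixes
    split between the two zones); "undetermined" without summer fixes.
    """
    season = seasons.assign_season(track.local_dates)
    s = track.fixes[season == seasons.SUMMER]
    if len(s) == 0:
        return "undetermined"
    if (s["lat"] >= breeding_lat).any():
        return "within" if not (s["lat"] < outside_lat).any() else "mixed"
    if (s["lat"] < outside_lat).all():
        return "outside"
    return "mixed"


# re-exported for convenience: season assignment is part of the phenology surface
assign_season = seasons.assign_season
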
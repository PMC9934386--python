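"""Ground-truth synthetic GPS cohorts for an Arctic-gull annual cycle.

Each simulated bird-year runs: winter residence on the Korea/Japan coast ->
spring migration along a coastal corridor of waypoints (scripted travel
days around 300 km/day, interleaved with stopovers) -> summer residence in
Arctic Siberia -> a slower, stopover-rich autumn migration back -> winter
residence.  Movement between waypoints is emitted as great-circle hops;
residence and stopovers are zero-mean few-km wander.  Fixes are sampled at
the configured duty cycle anchored at local (UTC+9) midnight, with
configurable per-fix jitter, failed (0/0) attempts and duplicate uploads.

Every stochastic choice flows from one seed, so identical configurations
reproduce byte-identical cohorts, and the generator records its own ground
truth (true daily distances and latitudes, derived migration windows,
injected artifact counts, diel intent of travel days) for every bird-year,
which is what the analysis stages are tested against.

The default parameters are the study conditions the emulation targets:
spring departures around late April with a few-day spread, autumn
departures spread from late August onward, travel-day speeds around
300 km/day, more and longer stopovers in autumn than in spring, migration
movement scheduled mostly in day/twilight hours, and migration altitudes
well above the near-sea-level residence baseline with rare >1000 m
excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from . import geodesy, seasons
from .table1 import load_table1
from .track_store import Deployment, Track

KM_PER_DEG_LAT = 111.195  # spherical: pi/180 * R

DEFAULT_BREEDING_SITES = (
    (68.833, 170.500),  # Chaun Delta
    (69.0, 160.5),
    (67.4, 153.0),
    (66.0, 158.5),
    (68.2, 146.0),
    (65.6, 171.0),
    (66.9, 152.5),
)
DEFAULT_WINTERING_SITES = (
    (37.390, 129.240),  # Samcheok
    (36.376, 129.401),  # Yeongdeok
    (35.45, 129.55),
    (38.45, 128.65),
    (39.9, 127.9),
    (43.0, 141.2),      # Hokkaido
    (35.9, 140.6),      # Honshu east coast
)
#: summering area of non-breeding birds, outside the breeding range
NONBREEDER_SUMMER_SITE = (55.0, 142.5)

#: baseline coastal corridor shared by all routes (Sea of Japan -> Sakhalin
#: -> Sea of Okhotsk north coast), offset per bird and jittered per year
CORRIDOR_WAYPOINTS = ((42.0, 131.3), (47.5, 141.0), (53.5, 141.5), (59.4, 150.9))


@dataclass
class SyntheticConfig:
    n_birds: int = 10
    years: int = 1
    start_year: int = 2016
    duty_cycle_h: float = 2.0
    breeding_sites: tuple = DEFAULT_BREEDING_SITES
    wintering_sites: tuple = DEFAULT_WINTERING_SITES
    n_nonbreeders: int = 0
    spring_departure_doy_mean: float = 114.0   # ~24 April
    spring_departure_doy_sd: float = 6.0
    autumn_departure_doy_mean: float = 237.0   # ~25 August
    autumn_departure_doy_sd: float = 15.0
    travel_speed_kmday_mean: float = 300.0
    travel_speed_kmday_sd: float = 50.0
    travel_speed_kmday_min: float = 120.0
    spring_stopover_mean: float = 1.0          # Poisson stopover count
    spring_stopover_days_mean: float = 3.0
    autumn_stopover_mean: float = 4.0
    autumn_stopover_days_mean: float = 6.0
    day_migration_prob: float = 0.9            # else movement in evening/night hours
    mig_altitude_mean_m: float = 300.0
    mig_altitude_sd_m: float = 150.0
    high_altitude_prob: float = 0.004          # rare 1000-3500 m excursions
    base_altitude_mean_m: float = 10.0
    base_altitude_sd_m: float = 15.0           # negatives occur, as in raw GPS data
    fix_failure_rate: float = 0.01
    duplicate_rate: float = 0.005
    route_noise_km: float = 10.0               # per-year waypoint jitter
    individual_route_offset_km: float = 50.0   # persistent per-bird corridor shift
    stopover_wander_km: float = 5.0
    gps_jitter_km: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fix_failure_rate", "duplicate_rate", "day_migration_prob",
                     "high_altitude_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duty_cycle_h <= 0 or self.travel_speed_kmday_mean <= 0:
            raise ValueError("duty cycle and travel speed must be positive")

    def quiet(self) -> "SyntheticConfig":
        """Copy with every noise and artifact source switched off."""
        d = asdict(self)
        d.update(route_noise_km=0.0, stopover_wander_km=0.0, gps_jitter_km=0.0,
                 fix_failure_rate=0.0, duplicate_rate=0.0)
        d["breeding_sites"] = self.breeding_sites
        d["wintering_sites"] = self.wintering_sites
        return SyntheticConfig(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("breeding_sites", "wintering_sites"):
            if key in d:
                d[key] = tuple(tuple(p) for p in d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generator-side truth the analysis stages are validated against."""

    birds: pd.DataFrame     # bird_id, breeder, age_class, site lat/lon columns
    daily: pd.DataFrame     # bird_id, date, true_km, true_mean_lat, true_active
    windows: pd.DataFrame   # bird_id, year, season, departure, arrival (active-day rule)
    travel_days: pd.DataFrame  # bird_id, date, mover ('day'|'night'), scripted_km
    injected: pd.DataFrame  # bird_id, failed, duplicate

    def to_json(self, path) -> None:
        payload = {
            "birds": self.birds.to_dict(orient="records"),
            "daily": self.daily.assign(date=self.daily["date"].astype(str)).to_dict(orient="records"),
            "windows": self.windows.assign(
                departure=self.windows["departure"].astype(str),
                arrival=self.windows["arrival"].astype(str),
            ).to_dict(orient="records"),
            "travel_days": self.travel_days.assign(
                date=self.travel_days["date"].astype(str)
            ).to_dict(orient="records"),
            "injected": self.injected.to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh)


def _offset_point(lat, lon, dx_km, dy_km):
    lat2 = lat + dy_km / KM_PER_DEG_LAT
    lon2 = lon + dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return float(lat2), float(geodesy.wrap_lon(lon2))


class _AnchorPath:
    """Timestamped waypoint path for one bird; times in seconds since epoch (UTC)."""

    def __init__(self):
        self.t: list[float] = []
        self.lat: list[float] = []
        self.lon: list[float] = []
        self.migrating: list[bool] = []  # flag of the segment STARTING at this anchor

    def add(self, t_s: float, lat: float, lon: float, migrating: bool = False):
        if self.t and t_s < self.t[-1] - 1e-9:
            raise ValueError("anchor times must be non-decreasing")
        if self.t and abs(t_s - self.t[-1]) < 1e-9:
            return  # coincident anchor; keep the earlier one
        self.t.append(t_s)
        self.lat.append(lat)
        self.lon.append(lon)
        self.migrating.append(migrating)

    def arrays(self):
        return (np.asarray(self.t), np.asarray(self.lat), np.asarray(self.lon),
                np.asarray(self.migrating, dtype=bool))

    def sample(self, times_s: np.ndarray):
        """Positions (lat, lon) and in-migration flags at arbitrary instants."""
        t, lat, lon, mig = self.arrays()
        idx = np.clip(np.searchsorted(t, times_s, side="right") - 1, 0, len(t) - 2)
        dt = t[idx + 1] - t[idx]
        frac = np.where(dt > 0, (times_s - t[idx]) / np.where(dt > 0, dt, 1.0), 0.0)
        frac = np.clip(frac, 0.0, 1.0)
        la, lo = geodesy.interpolate_on_great_circle(lat[idx], lon[idx], lat[idx + 1], lon[idx + 1], frac)
        return np.atleast_1d(la), np.atleast_1d(lo), mig[idx]

    def daily_true_km(self) -> pd.Series:
        """Path length per UTC+9 date, each segment charged to its start date."""
        t, lat, lon, _ = self.arrays()
        seg_km = geodesy.great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
        start = pd.to_datetime(t[:-1], unit="s", utc=True)
        dates = seasons.to_local_dates(start)
        return pd.Series(seg_km).groupby(dates).sum()


def _epoch_s(ts: pd.Timestamp) -> float:
    return ts.value / 1e9


def _kst(y: int, m: int, d: int, hour_frac: float = 0.0) -> float:
    base = pd.Timestamp(y, m, d, tz=seasons.KST_NAME) + pd.Timedelta(hours=hour_frac)
    return _epoch_s(base.tz_convert("UTC"))


def _plan_migration(rng, length_km, cfg, season):
    """Scripted day plan: list of ('travel', km, mover) / ('stop', days)."""
    speeds = []
    while sum(speeds) < length_km:
        speeds.append(
            max(cfg.travel_speed_kmday_min,
                rng.normal(cfg.travel_speed_kmday_mean, cfg.travel_speed_kmday_sd))
        )
    speeds = np.asarray(speeds) * (length_km / sum(speeds))
    n_stop = rng.poisson(cfg.spring_stopover_mean if season == "spring" else cfg.autumn_stopover_mean)
    stop_days_mean = (cfg.spring_stopover_days_mean if season == "spring"
                      else cfg.autumn_stopover_days_mean)
    plan = [("travel", float(km), "day" if rng.random() < cfg.day_migration_prob else "night")
            for km in speeds]
    if len(plan) > 1:
        for _ in range(n_stop):
            days = int(1 + rng.poisson(max(stop_days_mean - 1.0, 0.0)))
            pos = int(rng.integers(1, len(plan)))
            plan.insert(pos, ("stop", days))
    return plan


def _route_cumdist(points):
    lats = np.array([p[0] for p in points])
    lons = np.array([p[1] for p in points])
    seg = geodesy.great_circle_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    return np.concatenate([[0.0], np.cumsum(seg)]), lats, lons


def _route_position(cum, lats, lons, s_km):
    """Position at along-route distance s_km on the piecewise great-circle route."""
    s = float(np.clip(s_km, 0.0, cum[-1]))
    i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2))
    seg_len = cum[i + 1] - cum[i]
    frac = 0.0 if seg_len <= 0 else (s - cum[i]) / seg_len
    la, lo = geodesy.interpolate_on_great_circle(lats[i], lons[i], lats[i + 1], lons[i + 1], frac)
    return float(np.atleast_1d(la)[0]), float(np.atleast_1d(lo)[0]), i


DAY_MOVE_WINDOW = (8.0, 20.0)    # KST hours: day/twilight movement
NIGHT_MOVE_WINDOW = (19.0, 24.0)  # evening/night movement, kept within one date


def _emit_migration(path: _AnchorPath, rng, cfg, route_points, y, start_doy, plan, wander):
    """Append one migration's anchors; returns (arrival_doy_exclusive)."""
    cum, lats, lons = _route_cumdist(route_points)
    s = 0.0
    d = date(y, 1, 1) + timedelta(days=int(start_doy) - 1)
    for item in plan:
        if item[0] == "stop":
            for _ in range(item[1]):
                la, lo, _i = _route_position(cum, lats, lons, s)
                dx, dy = rng.normal(0.0, wander, 2) if wander > 0 else (0.0, 0.0)
                la, lo = _offset_point(la, lo, dx, dy)
                path.add(_kst(d.year, d.month, d.day), la, lo, False)
                d += timedelta(days=1)
            continue
        _, km, mover = item
        h0, h1 = DAY_MOVE_WINDOW if mover == "day" else NIGHT_MOVE_WINDOW
        la0, lo0, _ = _route_position(cum, lats, lons, s)
        path.add(_kst(d.year, d.month, d.day), la0, lo0, False)
        path.add(_kst(d.year, d.month, d.day, h0), la0, lo0, True)
        # insert waypoint crossings at constant along-route speed
        target = min(s + km, cum[-1])
        inner = cum[(cum > s + 1e-9) & (cum < target - 1e-9)]
        for c in inner:
            frac_t = (c - s) / (target - s)
            la, lo, _ = _route_position(cum, lats, lons, c)
            path.add(_kst(d.year, d.month, d.day, h0 + frac_t * (h1 - h0)), la, lo, True)
        la1, lo1, _ = _route_position(cum, lats, lons, target)
        path.add(_kst(d.year, d.month, d.day, h1), la1, lo1, False)
        s = target
        d += timedelta(days=1)
        if s >= cum[-1] - 1e-6:
            break
    return d.timetuple().tm_yday, d.year


def _residence(path: _AnchorPath, rng, site, y, doy0, doy1, wander):
    """Daily-wander residence anchors for days [doy0, doy1) of year y."""
    for doy in range(int(doy0), int(doy1)):
        d = date(y, 1, 1) + timedelta(days=doy - 1)
        dx, dy = rng.normal(0.0, wander, 2) if wander > 0 else (0.0, 0.0)
        la, lo = _offset_point(site[0], site[1], dx, dy)
        path.add(_kst(d.year, d.month, d.day), la, lo, False)


def generate_cohort(cfg: SyntheticConfig):
    """Simulate a cohort; returns (tracks, deployments, ground_truth).

    Tracks are raw (artifacts included) and ready for the filtering stage.
    """
    rng = np.random.default_rng(cfg.seed)
    tracks: list[Track] = []
    deployments: list[Deployment] = []
    bird_rows, window_rows, travel_rows, injected_rows = [], [], [], []
    daily_frames = []

    for b in range(cfg.n_birds):
        bird_id = f"syn{b:03d}"
        breeder = b >= cfg.n_nonbreeders
        wsite = cfg.wintering_sites[b % len(cfg.wintering_sites)]
        ssite = (cfg.breeding_sites[b % len(cfg.breeding_sites)] if breeder
                 else NONBREEDER_SUMMER_SITE)
        off_dx, off_dy = (rng.normal(0.0, cfg.individual_route_offset_km, 2)
                          if cfg.individual_route_offset_km > 0 else (0.0, 0.0))
        path = _AnchorPath()
        mover_by_day: dict[date, tuple[str, float]] = {}

        for year_i in range(cfg.years):
            y = cfg.start_year + year_i
            year_days = (date(y + 1, 1, 1) - date(y, 1, 1)).days
            # per-year jittered corridor (bird offset applied to every waypoint)
            waypoints = []
            for wla, wlo in CORRIDOR_WAYPOINTS:
                nx, ny = (rng.normal(0.0, cfg.route_noise_km, 2)
                          if cfg.route_noise_km > 0 else (0.0, 0.0))
                waypoints.append(_offset_point(wla, wlo, off_dx + nx, off_dy + ny))
            if not breeder:
                waypoints = [w for w in waypoints if w[0] < ssite[0] - 1.0]
            route_n = [wsite] + waypoints + [ssite]
            route_s = list(reversed(route_n))

            dep_spring = float(np.clip(
                rng.normal(cfg.spring_departure_doy_mean, cfg.spring_departure_doy_sd), 95, 135))
            dep_autumn = float(np.clip(
                rng.normal(cfg.autumn_departure_doy_mean, cfg.autumn_departure_doy_sd), 210, 280))

            length_km = _route_cumdist(route_n)[0][-1]
            plan_s = _plan_migration(rng, length_km, cfg, "spring")
            plan_a = _plan_migration(rng, length_km, cfg, "autumn")

            _residence(path, rng, wsite, y, 1, dep_spring, cfg.stopover_wander_km)
            arr_doy, arr_y = _emit_migration(path, rng, cfg, route_n, y, int(dep_spring),
                                             plan_s, cfg.stopover_wander_km)
            for item, doy in _iter_plan_days(plan_s, int(dep_spring)):
                if item[0] == "travel":
                    dd = date(y, 1, 1) + timedelta(days=doy - 1)
                    mover_by_day[dd] = (item[2], item[1])
            if arr_doy >= dep_autumn:
                raise ValueError("infeasible schedule: spring arrival after autumn departure")
            _residence(path, rng, ssite, y, arr_doy, dep_autumn, cfg.stopover_wander_km)
            arr2_doy, arr2_y = _emit_migration(path, rng, cfg, route_s, y, int(dep_autumn),
                                               plan_a, cfg.stopover_wander_km)
            for item, doy in _iter_plan_days(plan_a, int(dep_autumn)):
                if item[0] == "travel":
                    dd = date(y, 1, 1) + timedelta(days=doy - 1)
                    mover_by_day[dd] = (item[2], item[1])
            if arr2_y > y:
                raise ValueError("infeasible schedule: autumn migration spills past year end")
            _residence(path, rng, wsite, y, arr2_doy, year_days + 1, cfg.stopover_wander_km)

        # closing anchor so the final day is a defined segment
        end_y = cfg.start_year + cfg.years - 1
        path.add(_kst(end_y + 1, 1, 1), path.lat[-1], path.lon[-1], False)

        track, truth_daily, injected = _emit_fixes(path, rng, cfg, bird_id)
        tracks.append(track)
        deployments.append(
            Deployment(bird_id=bird_id, site="synthetic", tag_model="SYN-1",
                       duty_cycle_h=cfg.duty_cycle_h,
                       start=date(cfg.start_year, 1, 1), end=date(end_y, 12, 31),
                       age_class="adult" if breeder else "immature")
        )
        truth_daily["bird_id"] = bird_id
        daily_frames.append(truth_daily)
        window_rows.extend(_true_windows(truth_daily, bird_id))
        bird_rows.append(
            {"bird_id": bird_id, "breeder": breeder,
             "age_class": "adult" if breeder else "immature",
             "wintering_lat": wsite[0], "wintering_lon": wsite[1],
             "summering_lat": ssite[0], "summering_lon": ssite[1]}
        )
        travel_rows.extend(
            {"bird_id": bird_id, "date": pd.Timestamp(d), "mover": m, "scripted_km": km}
            for d, (m, km) in sorted(mover_by_day.items())
        )
        injected_rows.append({"bird_id": bird_id, **injected})

    truth = GroundTruth(
        birds=pd.DataFrame(bird_rows),
        daily=pd.concat(daily_frames, ignore_index=True),
        windows=pd.DataFrame(window_rows,
                             columns=["bird_id", "year", "season", "departure", "arrival"]),
        travel_days=pd.DataFrame(travel_rows, columns=["bird_id", "date", "mover", "scripted_km"]),
        injected=pd.DataFrame(injected_rows),
    )
    return tracks, deployments, truth


def _iter_plan_days(plan, start_doy):
    doy = int(start_doy)
    for item in plan:
        if item[0] == "stop":
            doy += item[1]
        else:
            yield item, doy
            doy += 1


def _emit_fixes(path: _AnchorPath, rng, cfg: SyntheticConfig, bird_id: str):
    t, _, _, _ = path.arrays()
    step_s = cfg.duty_cycle_h * 3600.0
    times = np.arange(t[0], t[-1] - 1e-6, step_s)
    lat, lon, moving = path.sample(times)

    # ground truth from the noiseless sampled path
    ts_utc = pd.to_datetime(times, unit="s", utc=True)
    dates = seasons.to_local_dates(ts_utc)
    v = geodesy._to_unit_vectors(lat, lon)
    gdf = pd.DataFrame({"date": dates, "x": v[:, 0], "y": v[:, 1], "z": v[:, 2]})
    g = gdf.groupby("date")[["x", "y", "z"]].mean()
    true_lat = np.degrees(np.arctan2(g["z"], np.hypot(g["x"], g["y"])))
    true_km = path.daily_true_km().reindex(g.index, fill_value=0.0)
    truth = pd.DataFrame({"date": g.index, "true_km": true_km.to_numpy(),
                          "true_mean_lat": true_lat.to_numpy()})
    truth["true_active"] = (
        (truth["true_km"] > 60.0)
        & (truth["true_mean_lat"] >= 40.9) & (truth["true_mean_lat"] <= 64.9)
    )

    if cfg.gps_jitter_km > 0:
        dx = rng.normal(0.0, cfg.gps_jitter_km, len(times))
        dy = rng.normal(0.0, cfg.gps_jitter_km, len(times))
        lat = lat + dy / KM_PER_DEG_LAT
        lon = geodesy.wrap_lon(lon + dx / (KM_PER_DEG_LAT * np.cos(np.radians(lat))))

    alt = rng.normal(cfg.base_altitude_mean_m, cfg.base_altitude_sd_m, len(times))
    mig_alt = np.abs(rng.normal(cfg.mig_altitude_mean_m, cfg.mig_altitude_sd_m, len(times)))
    high = rng.random(len(times)) < cfg.high_altitude_prob
    mig_alt = np.where(high, rng.uniform(1000.0, 3500.0, len(times)), mig_alt)
    alt = np.where(moving, mig_alt, alt)
    voltage = 4.1 + rng.normal(0.0, 0.02, len(times))

    failed = rng.random(len(times)) < cfg.fix_failure_rate
    lat_out = np.where(failed, 0.0, lat)
    lon_out = np.where(failed, 0.0, lon)

    fixes = pd.DataFrame({
        "bird_id": bird_id,
        "timestamp": ts_utc,
        "lat": lat_out, "lon": lon_out,
        "altitude_m": alt, "voltage_v": voltage,
    })
    # duplicates re-upload valid fixes only; a duplicated 0/0 row would be
    # indistinguishable from (and counted as) a second failed attempt
    dup_mask = (rng.random(len(times)) < cfg.duplicate_rate) & ~failed
    if dup_mask.any():
        dups = fixes[dup_mask]
        fixes = (
            pd.concat([fixes, dups], ignore_index=True)
            .sort_values("timestamp", kind="stable")
            .reset_index(drop=True)
        )
    injected = {"failed": int(failed.sum()), "duplicate": int(dup_mask.sum())}
    return Track(bird_id=bird_id, fixes=fixes), truth, injected


def _true_windows(truth_daily: pd.DataFrame, bird_id: str) -> list[dict]:
    act = truth_daily[truth_daily["true_active"]]
    if len(act) == 0:
        return []
    mseason = seasons.migration_season(act["date"])
    out = []
    years = pd.DatetimeIndex(act["date"]).year
    for (season, year), g in act.groupby([mseason, years]):
        if season is None:
            continue
        out.append({"bird_id": bird_id, "year": int(year), "season": season,
                    "departure": g["date"].min(), "arrival": g["date"].max()})
    return out


def write_cohort_csv(tracks, path) -> None:
    """Write a cohort in the canonical fix-table CSV dialect."""
    pd.concat([t.fixes for t in tracks], ignore_index=True).to_csv(path, index=False)


def generate_table1_fixture() -> pd.DataFrame:
    """The packaged verbatim 28-bird cohort summary table."""
    return load_table1()
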
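"""Fix tables, tracks, filtering, deployment bookkeeping and cohort summaries.

The atomic record is a *fix*: one GPS position for one bird.  In memory a
track is a pandas DataFrame with columns

    bird_id     str
    timestamp   tz-aware UTC
    lat, lon    decimal degrees (lon normalized to [-180, 180))
    altitude_m  metres above sea level, NaN when absent
    voltage_v   battery volts, NaN when absent

wrapped in a :class:`Track` carrying the bird id.  Fix-level filtering
removes failed location attempts (latitude and longitude both exactly 0)
and duplicate fixes, defined as two rows of the same bird with the same
timestamp (the standard logger upload artifact; identical coordinates at
different times are genuine stationarity and are kept).

Day counts use UTC+9 calendar dates, matching the deployment tables of the
Korean-programmed tags: the monitored span is (last date - first date) in
days, the convention that reproduces the printed per-bird day counts from
their start/end dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geodesy, seasons

FIX_COLUMNS = ["bird_id", "timestamp", "lat", "lon", "altitude_m", "voltage_v"]

#: Movebank-dialect column preset for :func:`read_fix_table`.
MOVEBANK_COLUMNS = {
    "individual-local-identifier": "bird_id",
    "timestamp": "timestamp",
    "location-lat": "lat",
    "location-long": "lon",
    "height-above-msl": "altitude_m",
    "tag-voltage": "voltage_v",
}


class ConfigurationError(ValueError):
    """A required input column or setting is missing."""


@dataclass
class Track:
    """Ordered fix sequence for one bird."""

    bird_id: str
    fixes: pd.DataFrame

    def __post_init__(self):
        if len(self.fixes) and not self.fixes["timestamp"].is_monotonic_increasing:
            self.fixes = self.fixes.sort_values("timestamp", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def local_dates(self) -> pd.DatetimeIndex:
        return seasons.to_local_dates(self.fixes["timestamp"])


@dataclass
class Deployment:
    bird_id: str
    site: str = "custom"
    tag_model: str = ""
    duty_cycle_h: float = 2.0
    start: date | None = None
    end: date | None = None
    age_class: str = "adult"          # adult | immature
    sex: str = "unknown"              # male | female | unknown
    tag_mass_g: float | None = None
    body_mass_g: float | None = None

    def __post_init__(self):
        if self.duty_cycle_h <= 0:
            raise ValueError("duty_cycle_h must be positive")


@dataclass
class RemovalReport:
    """Counts of fixes removed per filtering reason."""

    failed: int = 0
    duplicate: int = 0
    bad_rows: int = 0

    def as_dict(self) -> dict:
        return {"failed": self.failed, "duplicate": self.duplicate, "bad_rows": self.bad_rows}


@dataclass
class FateRecord:
    bird_id: str
    fate: str                       # dead_or_tag_lost | technical_failure | unknown | alive_at_censoring
    evidence: set = field(default_factory=set)


def read_fix_table(path, column_map: dict | None = None, tz_offset_h: float = 0.0):
    """Read a biologging CSV into per-bird time-sorted :class:`Track` objects.

    ``column_map`` maps file headers to canonical names (default: canonical
    headers already present; :data:`MOVEBANK_COLUMNS` covers the Movebank
    dialect).  ``tz_offset_h`` is the fixed UTC offset of naive timestamps
    in the file.  Malformed rows (unparseable timestamp or coordinates) are
    counted in the returned :class:`RemovalReport`, never silently dropped.

    Returns ``(tracks, report)`` with tracks ordered by bird id.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in ("bird_id", "timestamp", "lat", "lon") if c not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {missing}")
    for opt in ("altitude_m", "voltage_v"):
        if opt not in raw.columns:
            raw[opt] = np.nan
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="mixed")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(timezone(timedelta(hours=tz_offset_h)))
    ts = ts.dt.tz_convert("UTC")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    bad = ts.isna() | lat.isna() | lon.isna()
    report = RemovalReport(bad_rows=int(bad.sum()))
    df = pd.DataFrame(
        {
            "bird_id": raw["bird_id"].astype(str),
            "timestamp": ts,
            "lat": lat,
            "lon": geodesy.wrap_lon(lon),
            "altitude_m": pd.to_numeric(raw["altitude_m"], errors="coerce"),
            "voltage_v": pd.to_numeric(raw["voltage_v"], errors="coerce"),
        }
    )[~bad.to_numpy()]
    tracks = [
        Track(bird_id=bid, fixes=g.reset_index(drop=True))
        for bid, g in df.groupby("bird_id", sort=True)
    ]
    return tracks, report


def filter_fixes(track: Track) -> tuple[Track, RemovalReport]:
    """Remove failed (0/0) and duplicate-timestamp fixes.

    Duplicates keep the first occurrence.  Idempotent; the report satisfies
    ``len(out) + failed + duplicate == len(in)``.
    """
    f = track.fixes
    failed_mask = (f["lat"] == 0.0) & (f["lon"] == 0.0)
    kept = f[~failed_mask.to_numpy()]
    dup_mask = kept["timestamp"].duplicated(keep="first")
    out = kept[~dup_mask.to_numpy()].reset_index(drop=True)
    report = RemovalReport(failed=int(failed_mask.sum()), duplicate=int(dup_mask.sum()))
    return Track(bird_id=track.bird_id, fixes=out), report


def monitored_days(track: Track) -> int:
    """Monitored span in days: last minus first UTC+9 calendar date."""
    if len(track) == 0:
        return 0
    d = track.local_dates
    return int((d[-1] - d[0]).days)


def apply_inclusion_filter(tracks: Sequence[Track], min_days: int = 100):
    """Split tracks into (included, excluded) by monitored span >= min_days."""
    included = [t for t in tracks if monitored_days(t) >= min_days]
    excluded = [t for t in tracks if monitored_days(t) < min_days]
    return included, excluded


def classify_fate(
    track: Track,
    deployment: Deployment,
    study_end: date | None = None,
    stationary_days: float = 5.0,
    stationary_radius_km: float = 0.5,
    completeness_threshold: float = 0.80,
    voltage_threshold_v: float = 3.9,
) -> FateRecord:
    """Infer a bird's fate at the end of monitoring from a criteria tree.

    alive_at_censoring: still transmitting on the study end date;
    dead_or_tag_lost: every fix in the final ``stationary_days`` days lies
    within ``stationary_radius_km`` of their mean (terminal stationarity);
    technical_failure: fixes collected <= 80% of the duty-cycle expectation
    and/or last voltage <= 3.9 V; unknown otherwise.  Missing voltage skips
    the voltage criterion (noted in the evidence set).
    """
    f = track.fixes
    evidence: set = set()
    if len(f) == 0:
        return FateRecord(track.bird_id, "unknown", {"no_fixes"})
    last_ts = f["timestamp"].iloc[-1]
    if study_end is not None and seasons.to_local_dates(f["timestamp"][-1:])[0].date() >= study_end:
        return FateRecord(track.bird_id, "alive_at_censoring", {"transmitting_at_study_end"})

    window = f[f["timestamp"] >= last_ts - pd.Timedelta(days=stationary_days)]
    if len(window) >= 2:
        clat, clon = geodesy.spherical_mean(window["lat"], window["lon"])
        dists = geodesy.great_circle_km(window["lat"], window["lon"], clat, clon)
        if float(np.max(dists)) <= stationary_radius_km:
            evidence.add("terminal_stationarity")
            return FateRecord(track.bird_id, "dead_or_tag_lost", evidence)

    span_days = max(monitored_days(track), 1)
    expected = span_days * 24.0 / deployment.duty_cycle_h
    if len(f) / expected <= completeness_threshold:
        evidence.add("low_completeness")
    last_v = f["voltage_v"].iloc[-1]
    if pd.isna(last_v):
        evidence.add("voltage_unavailable")
    elif last_v <= voltage_threshold_v:
        evidence.add("low_voltage")
    if "low_completeness" in evidence or "low_voltage" in evidence:
        return FateRecord(track.bird_id, "technical_failure", evidence)
    return FateRecord(track.bird_id, "unknown", evidence)


def longest_summer_winter_km(track: Track) -> float:
    """Longest great-circle distance between any summer-band and winter-band fix.

    Exhaustive chunked pairwise scan; NaN when either season is unvisited.
    """
    f = track.fixes
    season = seasons.assign_season(track.local_dates)
    s = f[season == seasons.SUMMER]
    w = f[season == seasons.WINTER]
    if len(s) == 0 or len(w) == 0:
        return float("nan")
    best = 0.0
    slat, slon = s["lat"].to_numpy(), s["lon"].to_numpy()
    wlat, wlon = w["lat"].to_numpy(), w["lon"].to_numpy()
    for i in range(0, len(slat), 512):
        d = geodesy.great_circle_km(
            slat[i : i + 512, None], slon[i : i + 512, None], wlat[None, :], wlon[None, :]
        )
        best = max(best, float(d.max()))
    return best


def summarize_deployment(track: Track) -> dict:
    """Per-bird summary row: days, fixes, total track, daily rate, longest GC."""
    f = track.fixes
    n_days = monitored_days(track)
    total_km = geodesy.path_length_km(f["lat"].to_numpy(), f["lon"].to_numpy())
    return {
        "bird_id": track.bird_id,
        "n_days": n_days,
        "n_fixes": len(f),
        "total_track_km": total_km,
        "mean_km_per_day": total_km / n_days if n_days > 0 else float("nan"),
        "longest_gc_km": longest_summer_winter_km(track),
    }


def round_half_away(x, ndigits: int = 0):
    """Round half away from zero (the convention of the printed tables)."""
    x = np.asarray(x, float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.shape == () else out


def cohort_summary(rows: pd.DataFrame) -> dict:
    """Cohort-level totals and means over per-bird summary rows.

    ``rows`` needs columns n_days, n_fixes, total_track_km, longest_gc_km.
    Integer-reported means are rounded half away from zero; the grand mean
    km/day is total km over total days (not the mean of per-bird rates).
    """
    if len(rows) == 0:
        raise ValueError("cohort_summary of an empty cohort")
    total_days = int(rows["n_days"].sum())
    total_fixes = int(rows["n_fixes"].sum())
    total_km = float(rows["total_track_km"].sum())
    n = len(rows)
    longest = rows["longest_gc_km"].astype(float)
    return {
        "n_birds": n,
        "total_days": total_days,
        "total_fixes": total_fixes,
        "total_track_km": total_km,
        "mean_days_per_bird": total_days / n,
        "mean_fixes_per_bird": total_fixes / n,
        "mean_track_km_per_bird": total_km / n,
        "grand_mean_km_per_day": total_km / total_days if total_days else float("nan"),
        "longest_gc_mean_km": float(longest.mean()),
        "longest_gc_sd_km": float(longest.std(ddof=1)) if n > 1 else float("nan"),
        "longest_gc_min_km": float(longest.min()),
        "longest_gc_max_km": float(longest.max()),
    }


def _reaches_breeding_range_in_summer(track: Track, breeding_lat: float = 64.9) -> bool:
    season = seasons.assign_season(track.local_dates)
    s = track.fixes[season == seasons.SUMMER]
    return len(s) > 0 and bool((s["lat"] >= breeding_lat).any())


def _full_cycle_year(track: Track) -> int | None:
    """First calendar year with a pre-spring and a post-autumn winter fix."""
    d = track.local_dates
    if len(d) == 0:
        return None
    md = d.month * 100 + d.day
    for year in sorted(set(d.year)):
        pre = ((d.year == year) & (md <= 412)).any() or (
            ((d.year == year - 1) & (md >= 1218)).any()
        )
        post = ((d.year == year) & (md >= 1218)).any()
        if pre and post:
            return int(year)
    return None


def select_subsample(
    tracks: Sequence[Track],
    deployments: dict[str, Deployment] | Iterable[Deployment],
    rule: str,
    breeding_lat: float = 64.9,
) -> list[Track]:
    """Deterministic analysis subsamples.

    rule "A": adults that reached the breeding range (>= ``breeding_lat``)
    during the summer band.  rule "B": birds on a 2 h duty cycle.
    rule "C": birds monitored over a full spring + autumn migration cycle of
    the same year (a winter fix both before spring and after autumn); for
    multi-year birds only the first such year is retained, tracks trimmed to
    the end of that year's post-autumn winter window (12 Apr of year+1).
    """
    if not isinstance(deployments, dict):
        deployments = {d.bird_id: d for d in deployments}
    if rule == "A":
        return [
            t
            for t in tracks
            if deployments[t.bird_id].age_class == "adult"
            and _reaches_breeding_range_in_summer(t, breeding_lat)
        ]
    if rule == "B":
        return [t for t in tracks if deployments[t.bird_id].duty_cycle_h == 2]
    if rule == "C":
        out = []
        for t in tracks:
            year = _full_cycle_year(t)
            if year is None:
                continue
            cutoff = pd.Timestamp(year + 1, 4, 13, tz=seasons.KST_NAME).tz_convert("UTC")
            trimmed = t.fixes[t.fixes["timestamp"] < cutoff].reset_index(drop=True)
            out.append(Track(bird_id=t.bird_id, fixes=trimmed))
        return out
    raise ValueError(f"unknown subsample rule: {rule!r}")
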
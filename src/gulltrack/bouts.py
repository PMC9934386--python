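"""Standardized 2 h bouts: distances, rates, altitudes, diel classes.

A *bout* is the leg between two consecutive fixes of a 2 h duty-cycle
track.  Legs outside 1.9-2.1 h (missed or delayed fixes) are dropped so
that rates of travel are comparable across birds; a bout that covers more
than 5 km (strictly) is a *migration bout*.  The bout altitude is the mean
of its endpoint altitudes after flooring negatives (GPS altitude noise at
sea level) at zero; bouts missing an endpoint altitude keep NaN there and
still contribute to rate/diel analyses.

Rank-based comparisons (Mann-Whitney U between groups, Wilcoxon signed rank
for paired season contrasts) report a tie- and continuity-corrected normal
z alongside the p-value; small samples switch to exact enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import geodesy, seasons, solar
from .track_store import Track

BOUT_MIN_H = 1.9
BOUT_MAX_H = 2.1
MIGRATION_BOUT_KM = 5.0


@dataclass
class RankTestResult:
    test: str
    statistic_z: float
    p_value: float
    n1: int
    n2: int = 0


def bout_altitude(start_alt, end_alt):
    """Mean of the two endpoint altitudes with negatives floored at zero."""
    a = np.maximum(np.asarray(start_alt, float), 0.0)
    b = np.maximum(np.asarray(end_alt, float), 0.0)
    out = (a + b) / 2.0
    return float(out) if out.shape == () else out


def extract_bouts(
    track: Track,
    min_h: float = BOUT_MIN_H,
    max_h: float = BOUT_MAX_H,
    migration_km: float = MIGRATION_BOUT_KM,
    diel_threshold_deg: float = solar.CIVIL_TWILIGHT_DEG,
) -> pd.DataFrame:
    """One row per retained consecutive-fix pair.

    Columns: bird_id, start/end timestamps, duration_h, distance_km,
    rate_kmh, altitude_m (NaN if an endpoint altitude is missing),
    diel (from the solar elevation at each endpoint's own place and time),
    is_migration, month (start fix, UTC+9).
    """
    f = track.fixes
    if len(f) < 2:
        return pd.DataFrame(
            columns=["bird_id", "start", "end", "duration_h", "distance_km", "rate_kmh",
                     "altitude_m", "diel", "is_migration", "month"]
        )
    t = f["timestamp"].to_numpy()
    dur_h = (t[1:] - t[:-1]) / np.timedelta64(1, "h")
    keep = (dur_h >= min_h) & (dur_h <= max_h)
    i0 = np.flatnonzero(keep)
    i1 = i0 + 1
    lat, lon = f["lat"].to_numpy(), f["lon"].to_numpy()
    alt = f["altitude_m"].to_numpy(float)
    dist = geodesy.great_circle_km(lat[i0], lon[i0], lat[i1], lon[i1])
    dur = dur_h[i0]
    elev0 = solar.solar_elevation(lat[i0], lon[i0], pd.DatetimeIndex(t[i0], tz="UTC"))
    elev1 = solar.solar_elevation(lat[i1], lon[i1], pd.DatetimeIndex(t[i1], tz="UTC"))
    diel = solar.classify_diel(elev0, elev1, diel_threshold_deg)
    altitude = np.where(
        np.isnan(alt[i0]) | np.isnan(alt[i1]), np.nan, bout_altitude(alt[i0], alt[i1])
    )
    months = seasons.to_local_dates(pd.DatetimeIndex(t[i0], tz="UTC")).month
    return pd.DataFrame(
        {
            "bird_id": track.bird_id,
            "start": pd.DatetimeIndex(t[i0], tz="UTC"),
            "end": pd.DatetimeIndex(t[i1], tz="UTC"),
            "duration_h": dur,
            "distance_km": dist,
            "rate_kmh": dist / dur,
            "altitude_m": altitude,
            "diel": diel,
            "is_migration": dist > migration_km,
            "month": np.asarray(months),
        }
    )


def diel_composition(bouts: pd.DataFrame, subset: str = "all") -> pd.DataFrame:
    """Per-month proportions of day/twilight/night bouts.

    ``subset``: "all" or "migration_only".  Proportions per month sum to 1;
    the n_bouts column lets integer class counts be recovered exactly.
    """
    if subset == "migration_only":
        bouts = bouts[bouts["is_migration"]]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'migration_only'")
    counts = (
        bouts.groupby(["month", "diel"]).size().unstack(fill_value=0)
        .reindex(columns=[solar.DIEL_DAY, solar.DIEL_TWILIGHT, solar.DIEL_NIGHT], fill_value=0)
    )
    total = counts.sum(axis=1)
    props = counts.div(total, axis=0)
    props.columns = [f"prop_{c}" for c in props.columns]
    props["n_bouts"] = total
    return props.reset_index()


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values)


def _exact_mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating every assignment of pooled ranks.

    Handles ties through mid-ranks; feasible for both n <= 8.
    """
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n1 = len(a)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # observed U for group A
    mu = n1 * len(b) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney(a, b, exact_max_n: int = 8) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Normal approximation with tie correction and continuity correction;
    exact enumeration (tie-safe) when both samples have <= ``exact_max_n``
    observations.  Identical pooled values give p = 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n1 + n2) * (n1 + n2 - 1.0))
    var = n1 * n2 / 12.0 * ((n1 + n2 + 1.0) - tie_term)
    if var <= 0:  # every pooled value identical
        return RankTestResult("mann_whitney_u", 0.0, 1.0, n1, n2)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / math.sqrt(var) if u1 != mu else 0.0
    if n1 <= exact_max_n and n2 <= exact_max_n:
        p = _exact_mann_whitney_p(a, b)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return RankTestResult("mann_whitney_u", float(z), float(min(p, 1.0)), n1, n2)


def wilcoxon_signed_rank(differences, exact_max_n: int = 15) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment).  Exact
    enumeration of the 2^n sign assignments when n <= ``exact_max_n`` (the
    cutoff covers the 13-pair paired-season design), else the
    continuity-corrected normal approximation with tie correction.
    """
    d = np.asarray(differences, float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return RankTestResult("wilcoxon_signed_rank", 0.0, 1.0, 0)
    ranks = _midranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = 0.0 if var <= 0 else (w_pos - mu - 0.5 * np.sign(w_pos - mu)) / math.sqrt(var)
    if n <= exact_max_n:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        w_all = bits @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= abs(w_pos - mu) - 1e-12))
    else:
        p = 2.0 * stats.norm.sf(abs(z)) if var > 0 else 1.0
    return RankTestResult("wilcoxon_signed_rank", float(z), float(min(p, 1.0)), n)
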
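"""Between-year route consistency via Dynamic Time Warping.

Tracks are normalized to daily positions, cut into the four season bands,
projected into a common Lambert azimuthal equal-area plane, and compared
pairwise with classic unconstrained DTW: the minimum, over all monotone
boundary-matched alignments, of the summed pointwise distances.  Larger
values mean more dissimilar routes; DTW tolerates segments of different
lengths and speeds, which is why it suits animal tracks.

Within-individual (same bird, different years) and between-individual
distributions of DTW values are compared with a label-permutation test on
the difference of group means.  The point metric defaults to planar
Euclidean km in the common LAEA plane (scale-meaningful and safe across
the antimeridian); great-circle point costs are available as an option.
DTW values are raw cumulative distances; an option normalizes by path
length for cross-length comparability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import geodesy, seasons


@dataclass
class SeasonalSegment:
    """Daily positions of one bird-season-year, with projected coordinates."""

    bird_id: str
    year: int
    season: str
    lat: np.ndarray
    lon: np.ndarray
    xy_km: np.ndarray  # (n, 2) in the common LAEA plane


@dataclass
class DTWResult:
    seg_a: str
    seg_b: str
    value: float
    same_individual: bool


@dataclass
class PermutationResult:
    observed_diff: float
    n_perm: int
    p_value: float
    seed: int


def dtw(a: np.ndarray, b: np.ndarray, normalize: bool = False) -> float:
    """Classic DTW dissimilarity between two point sequences, shape (n, d).

    Pointwise cost is Euclidean distance; the cumulative cost uses the
    standard (insertion, deletion, match) recursion with matched endpoints
    and no warping window.  ``normalize`` divides by the warping-path
    length for comparisons across very different segment lengths.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw of an empty segment")
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    n, m = cost.shape
    D = np.full((n + 1, m + 1), np.inf)
    steps = np.zeros((n + 1, m + 1), dtype=np.int64)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row_c = cost[i - 1]
        prev = D[i - 1]
        cur = D[i]
        sprev = steps[i - 1]
        scur = steps[i]
        for j in range(1, m + 1):
            best = prev[j - 1]
            s = sprev[j - 1]
            if prev[j] < best:
                best, s = prev[j], sprev[j]
            if cur[j - 1] < best:
                best, s = cur[j - 1], scur[j - 1]
            cur[j] = best + row_c[j - 1]
            scur[j] = s + 1
    value = float(D[n, m])
    return value / steps[n, m] if normalize else value


def seasonal_segments(
    daily: pd.DataFrame,
    projection: geodesy.LaeaProjection | None = None,
    min_points: int = 2,
) -> list[SeasonalSegment]:
    """Cut daily positions into per-bird season-year segments.

    ``daily`` needs columns bird_id, date (UTC+9 calendar date), lat, lon.
    All segments share one projection (default: centred on the spherical
    mean of every input position).  December winter days are grouped with
    the following year's winter.
    """
    if projection is None:
        projection = geodesy.laea_for_points(daily["lat"], daily["lon"])
    daily = daily.copy()
    daily["season"] = seasons.assign_season(daily["date"])
    daily["season_year"] = seasons.season_year(daily["date"])
    out = []
    for (bird, season, year), g in daily.groupby(["bird_id", "season", "season_year"], sort=True):
        if len(g) < min_points:
            continue
        g = g.sort_values("date")
        x, y = projection.forward(g["lat"].to_numpy(), g["lon"].to_numpy())
        out.append(
            SeasonalSegment(
                bird_id=bird, year=int(year), season=season,
                lat=g["lat"].to_numpy(), lon=g["lon"].to_numpy(),
                xy_km=np.column_stack([x, y]),
            )
        )
    return out


def seasonal_dtw_sets(
    segments: list[SeasonalSegment], season: str, normalize: bool = False
) -> tuple[list[DTWResult], list[DTWResult]]:
    """(within-individual, between-individual) DTW values for one season.

    Every unordered segment pair is compared once; same-bird pairs are
    necessarily different years.
    """
    segs = [s for s in segments if s.season == season]
    within, between = [], []
    for sa, sb in combinations(segs, 2):
        res = DTWResult(
            seg_a=f"{sa.bird_id}/{sa.year}", seg_b=f"{sb.bird_id}/{sb.year}",
            value=dtw(sa.xy_km, sb.xy_km, normalize=normalize),
            same_individual=sa.bird_id == sb.bird_id,
        )
        (within if res.same_individual else between).append(res)
    return within, between


def permutation_diff_test(group_a, group_b, n_perm: int = 10_000, seed: int = 0) -> PermutationResult:
    """Two-sided permutation test on the difference of group means.

    The null distribution reshuffles group labels over the pooled values;
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1), which avoids p = 0
    and is exactly reproducible for a fixed seed.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    observed = a.mean() - b.mean()
    # sorted pool makes the null depend only on the value multiset, so the
    # p-value is invariant to input order within groups
    pooled = np.sort(np.concatenate([a, b]))
    if pooled[0] == pooled[-1]:
        return PermutationResult(0.0, n_perm, 1.0, seed)
    rng = np.random.default_rng(seed)
    n_a, n_tot = len(a), len(pooled)
    # vectorized label reshuffles: argsort of uniforms gives random permutations
    count = 0
    chunk = max(1, min(n_perm, int(2e7) // max(n_tot, 1)))
    done = 0
    total = pooled.sum()
    while done < n_perm:
        k = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((k, n_tot)), axis=1)
        sum_a = pooled[idx[:, :n_a]].sum(axis=1)
        diffs = sum_a / n_a - (total - sum_a) / (n_tot - n_a)
        count += int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
        done += k
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(float(observed), n_perm, float(p), seed)


def timing_consistency(windows: list, bird_id: str, year1: int, year2: int) -> dict:
    """Absolute day-of-year shifts of migration timing between two years.

    Returns whichever of spring_start/spring_end/autumn_start/autumn_end
    endpoints exist in both years' individual windows.  Day-of-year is
    evaluated on a fixed non-leap calendar so the same calendar date in a
    leap and a non-leap year counts as a zero-day shift.
    """
    def doy(ts: pd.Timestamp) -> int:
        return int(pd.Timestamp(2001, ts.month, ts.day).dayofyear)

    def lookup(season, year):
        for w in windows:
            if w.bird_id == bird_id and w.season == season and w.year == year:
                return w
        return None

    out = {}
    for season in (seasons.SPRING, seasons.AUTUMN):
        w1, w2 = lookup(season, year1), lookup(season, year2)
        if w1 is None or w2 is None:
            continue
        out[f"{season}_start"] = abs(doy(w1.first_active) - doy(w2.first_active))
        out[f"{season}_end"] = abs(doy(w1.last_active) - doy(w2.last_active))
    return out
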
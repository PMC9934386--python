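"""Migratory connectivity: Mantel correlation of seasonal centroid distances.

Strong connectivity means birds that breed close together also winter
close together.  Each bird contributes one breeding centroid (spherical
mean of its summer-band fixes) and one wintering centroid (winter-band
fixes); the Mantel statistic is the Pearson correlation between the
strictly-lower-triangle entries of the two pairwise great-circle distance
matrices.  Confidence intervals resample birds with replacement
(percentile bootstrap, both matrices rebuilt per resample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geodesy, seasons
from .track_store import Track


@dataclass
class MantelResult:
    r_mantel: float
    ci_low: float
    ci_high: float
    n_birds: int
    n_boot: int
    seed: int


def seasonal_centroids(tracks) -> pd.DataFrame:
    """Per-bird breeding (summer band) and wintering (winter band) centroids.

    Birds lacking fixes in either band are excluded.
    """
    rows = []
    for t in tracks:
        season = seasons.assign_season(t.local_dates)
        row = {"bird_id": t.bird_id}
        ok = True
        for label, band in (("breeding", seasons.SUMMER), ("wintering", seasons.WINTER)):
            sel = t.fixes[season == band]
            if len(sel) == 0:
                ok = False
                break
            la, lo = geodesy.spherical_mean(sel["lat"], sel["lon"])
            row[f"{label}_lat"], row[f"{label}_lon"] = la, lo
        if ok:
            rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    return geodesy.great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel_r(d_breed: np.ndarray, d_winter: np.ndarray) -> float:
    """Pearson correlation of the strictly-lower triangles of two distance matrices."""
    a = _lower_triangle(np.asarray(d_breed, float))
    b = _lower_triangle(np.asarray(d_winter, float))
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Mantel r undefined: zero variance in a distance matrix")
    return float(np.corrcoef(a, b)[0, 1])


def mantel_connectivity(
    centroids: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MantelResult:
    """Mantel correlation between breeding and wintering distance matrices.

    ``centroids`` as returned by :func:`seasonal_centroids` (>= 3 birds).
    The bootstrap resamples birds with replacement, jointly re-indexing
    rows and columns of both matrices; degenerate resamples with fewer
    than 3 unique birds are redrawn.
    """
    n = len(centroids)
    if n < 3:
        raise ValueError("Mantel connectivity needs at least 3 birds")
    db = _pairwise_km(centroids["breeding_lat"].to_numpy(), centroids["breeding_lon"].to_numpy())
    dw = _pairwise_km(centroids["wintering_lat"].to_numpy(), centroids["wintering_lon"].to_numpy())
    r = mantel_r(db, dw)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(idx)) >= 3:
                sub_b = db[np.ix_(idx, idx)]
                sub_w = dw[np.ix_(idx, idx)]
                tri_b = _lower_triangle(sub_b)
                tri_w = _lower_triangle(sub_w)
                if np.std(tri_b) > 0 and np.std(tri_w) > 0:
                    break
        boot[i] = np.corrcoef(tri_b, tri_w)[0, 1]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return MantelResult(r_mantel=r, ci_low=float(lo), ci_high=float(hi),
                        n_birds=n, n_boot=n_boot, seed=seed)
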
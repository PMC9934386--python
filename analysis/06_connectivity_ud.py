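"""Migratory connectivity (Mantel) and seasonal utilization distributions.

From the simulated cohort: per-bird breeding and wintering centroids, the
Mantel correlation between their pairwise-distance matrices with a
1000-resample bootstrap CI, and seasonal 100-km kernel UDs on first-year
daily positions (50% and 95% isopleth areas).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gulltrack import connectivity, geodesy, kernel_ud, seasons, track_store

IN = Path("scratch/cohort/fixes.csv")
OUT = Path("results/connectivity_ud")
SEED = 2018


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tracks, _ = track_store.read_fix_table(IN)
    tracks = [track_store.filter_fixes(t)[0] for t in tracks]

    cents = connectivity.seasonal_centroids(tracks)
    cents.to_csv(OUT / "seasonal_centroids.csv", index=False)
    res = connectivity.mantel_connectivity(cents, n_boot=1000, seed=SEED)
    pd.DataFrame([vars(res)]).to_csv(OUT / "mantel.csv", index=False)
    print(f"migratory connectivity: Mantel r = {res.r_mantel:.3f} "
          f"(95% CI {res.ci_low:.2f} to {res.ci_high:.2f}, "
          f"{res.n_birds} birds, {res.n_boot} bootstraps)")

    frames = []
    for t in tracks:
        rt = geodesy.regularize(t.fixes, "1D", bird_id=t.bird_id)
        frames.append(pd.DataFrame({
            "bird_id": t.bird_id,
            "date": seasons.to_local_dates(rt.positions["timestamp"]),
            "lat": rt.positions["lat"], "lon": rt.positions["lon"]}))
    daily = pd.concat(frames, ignore_index=True)
    proj = geodesy.laea_for_points(daily["lat"], daily["lon"])

    rows = []
    for season in ("winter", "spring", "summer", "autumn"):
        sel = daily[seasons.assign_season(daily["date"]) == season]
        x, y = proj.forward(sel["lat"].to_numpy(), sel["lon"].to_numpy())
        grid = kernel_ud.utilization_distribution(
            np.column_stack([x, y]), smoothing_km=100.0, cell_km=50.0)
        rows.append({"season": season, "n_positions": len(sel),
                     "area50_km2": kernel_ud.isopleth_area_km2(grid, 0.5),
                     "area95_km2": kernel_ud.isopleth_area_km2(grid, 0.95)})
        print(f"{season:7s} UD: {len(sel):5d} daily positions, "
              f"50% isopleth {rows[-1]['area50_km2']/1e3:.0f} thousand km2, "
              f"95% {rows[-1]['area95_km2']/1e6:.2f} million km2")
    pd.DataFrame(rows).to_csv(OUT / "ud_isopleth_areas.csv", index=False)


if __name__ == "__main__":
    main()
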
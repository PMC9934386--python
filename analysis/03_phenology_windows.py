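"""Migration phenology: active days, migratory windows, route fractions.

Classifies active migration days (>60 km/day between 40.9 and 64.9 deg N),
derives individual and population migratory windows per season, compares
spring and autumn with a paired Wilcoxon test, and reports the share of
the route covered on active days.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gulltrack import phenology, track_store
from gulltrack.bouts import wilcoxon_signed_rank

IN = Path("scratch/cohort/fixes.csv")
OUT = Path("results/phenology")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tracks, _ = track_store.read_fix_table(IN)
    tracks = [track_store.filter_fixes(t)[0] for t in tracks]
    daily = pd.concat([phenology.daily_series(t) for t in tracks], ignore_index=True)
    daily = phenology.classify_active_days(daily)
    Path("scratch").mkdir(exist_ok=True)
    daily.to_csv(Path("scratch") / "daily_series.csv", index=False)

    windows = phenology.individual_windows(daily)
    wdf = pd.DataFrame([
        {"bird_id": w.bird_id, "season": w.season, "year": w.year,
         "first_active": w.first_active, "last_active": w.last_active,
         "duration_days": w.duration_days, "n_active_days": w.n_active_days,
         "prop_active": w.prop_active,
         "route_fraction_active": phenology.route_fraction_on_active_days(daily, w)}
        for w in windows
    ])
    wdf.to_csv(OUT / "individual_windows.csv", index=False)

    paired = wdf.pivot_table(index="bird_id", columns="season", values="duration_days")
    paired = paired.dropna()
    res = wilcoxon_signed_rank(paired["spring"] - paired["autumn"])
    sp, au = wdf[wdf.season == "spring"], wdf[wdf.season == "autumn"]
    print(f"individual windows: spring median {sp['duration_days'].median():.0f} d "
          f"vs autumn {au['duration_days'].median():.0f} d "
          f"(paired Wilcoxon z={res.statistic_z:.2f}, p={res.p_value:.4f}, n={res.n1})")
    print(f"proportion of window on active migration: spring {sp['prop_active'].mean():.2f}, "
          f"autumn {au['prop_active'].mean():.2f}")
    print(f"route fraction covered on active days: "
          f"{wdf['route_fraction_active'].mean():.2f} on average")

    rows = []
    for season in ("spring", "autumn"):
        for year in sorted(daily["date"].dt.year.unique()):
            pw = phenology.population_window(daily, season, int(year))
            if pw:
                rows.append({"season": season, "year": year,
                             "first": pw.first_active, "last": pw.last_active,
                             "duration_days": pw.duration_days})
    pd.DataFrame(rows).to_csv(OUT / "population_windows.csv", index=False)
    print(f"population windows written for {len(rows)} season-years -> {OUT}/")


if __name__ == "__main__":
    main()
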
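"""2 h bouts: diel composition, rates of travel and flight altitudes.

Extracts standardized 2 h bouts from the 2 h duty-cycle birds, classifies
each as day/twilight/night from the solar elevation at its endpoints,
flags migration bouts (>5 km), and contrasts rates and altitudes between
migration and other bouts with Mann-Whitney tests.
"""

from pathlib import Path

import pandas as pd

from gulltrack import track_store
from gulltrack.bouts import diel_composition, extract_bouts, mann_whitney

IN = Path("scratch/cohort/fixes.csv")
OUT = Path("results/bouts")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tracks, _ = track_store.read_fix_table(IN)
    tracks = [track_store.filter_fixes(t)[0] for t in tracks]
    bouts = pd.concat([extract_bouts(t) for t in tracks], ignore_index=True)
    Path("scratch").mkdir(exist_ok=True)
    bouts.to_csv(Path("scratch") / "bouts.csv", index=False)
    for subset in ("all", "migration_only"):
        diel_composition(bouts, subset).to_csv(
            OUT / f"diel_composition_{subset}.csv", index=False)

    mig = bouts[bouts["is_migration"]]
    other = bouts[~bouts["is_migration"]]
    night_share = (mig["diel"] == "night").mean()
    print(f"{len(bouts)} retained 2 h bouts, {len(mig)} migration bouts "
          f"({night_share:.0%} of migration bouts at night)")

    r = mann_whitney(mig["rate_kmh"], other["rate_kmh"])
    print(f"rates of travel: migration median {mig['rate_kmh'].median():.1f} km/h vs "
          f"other {other['rate_kmh'].median():.1f} km/h (z={r.statistic_z:.1f}, "
          f"p={r.p_value:.2g})")
    a = mann_whitney(mig["altitude_m"].dropna(), other["altitude_m"].dropna())
    print(f"altitudes: migration median {mig['altitude_m'].median():.0f} m vs "
          f"other {other['altitude_m'].median():.0f} m (z={a.statistic_z:.1f}, "
          f"p={a.p_value:.2g}); tables -> {OUT}/")


if __name__ == "__main__":
    main()
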
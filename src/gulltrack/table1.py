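"""Packaged per-bird deployment summary table for the 28-gull study cohort.

A verbatim transcription of the published per-bird summary columns (ids,
monitoring dates and day counts, filtered fix counts, duty cycles, total
track lengths, mean daily distances, longest summer-winter great-circle
distances).  It is the arithmetic validation surface for the cohort-summary
code: the totals and means the cohort table prints must be recomputable
exactly from its per-row cells.

Note one internal inconsistency of the printed source, kept as printed: the
results text gives a total-distance range of "6531-51,010 km" while the
per-row minimum is 1860 km (ke1513).  The per-row values are authoritative
here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NUMERIC = ["n_days", "n_fixes", "total_track_km", "mean_km_per_day", "longest_gc_km"]


def load_table1() -> pd.DataFrame:
    """The packaged cohort table as a DataFrame, one row per bird (n = 28)."""
    with resources.files("gulltrack.data").joinpath("table1_vega_gulls.csv").open() as fh:
        df = pd.read_csv(fh, parse_dates=["start_date", "end_date"])
    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col])
    return df
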
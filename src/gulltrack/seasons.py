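"""Season bands of the annual cycle and UTC+9 calendar conventions.

The analysis slices the year into four fixed bands:

    winter  18 Dec - 12 Apr   (wraps the year boundary)
    spring  13 Apr -  6 Jun   (spring migration window)
    summer   7 Jun - 31 Aug   (breeding residence)
    autumn   1 Sep - 17 Dec   (autumn migration window)

These partition the year with no overlap.  All calendar-day bookkeeping
(dates, months, day counts) uses UTC+9, the local time of the Korean
wintering range where the tags were deployed.
"""

from __future__ import annotations

from datetime import timedelta, timezone

import numpy as np
import pandas as pd

TZ_OFFSET_H = 9
KST = timezone(timedelta(hours=TZ_OFFSET_H))
#: pandas/pytz name for the fixed UTC+9 offset (Etc/GMT signs are reversed)
KST_NAME = "Etc/GMT-9"

WINTER, SPRING, SUMMER, AUTUMN = "winter", "spring", "summer", "autumn"

# band boundaries as (month, day) of the first day of each band
_SPRING_START = (4, 13)
_SUMMER_START = (6, 7)
_AUTUMN_START = (9, 1)
_WINTER_START = (12, 18)


def _mmdd(dates):
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[D]")))
    return d.month * 100 + d.day


def assign_season(dates):
    """Season label(s) for calendar date(s); winter wraps the year boundary."""
    md = _mmdd(dates)
    out = np.full(md.shape, WINTER, dtype=object)
    out[(md >= 413) & (md < 607)] = SPRING
    out[(md >= 607) & (md < 901)] = SUMMER
    out[(md >= 901) & (md < 1218)] = AUTUMN
    return out[0] if np.isscalar(dates) or getattr(dates, "ndim", 0) == 0 else out


def season_year(dates):
    """Year label of the season a date belongs to.

    December winter dates are assigned to the following year so that one
    winter (Dec 18 - Apr 12) carries a single label: the year of its
    January-April part.
    """
    d = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[D]")))
    md = d.month * 100 + d.day
    yr = d.year.to_numpy().copy()
    yr[md >= 1218] += 1
    return yr[0] if np.isscalar(dates) or getattr(dates, "ndim", 0) == 0 else yr


def migration_season(dates):
    """Spring/autumn assignment for active-migration days.

    Active days before the summer band (7 Jun) belong to spring; active
    days from 1 Jul onward belong to autumn (the earliest autumn departures
    from the breeding range fall in late July, well after the last spring
    arrivals in early June, so the mid-summer pivot is unambiguous); days
    in the short 7-30 Jun dead zone return None.
    """
    md = _mmdd(dates)
    out = np.full(md.shape, None, dtype=object)
    out[md < 607] = SPRING
    out[md >= 701] = AUTUMN
    return out[0] if np.isscalar(dates) or getattr(dates, "ndim", 0) == 0 else out


def to_local_dates(timestamps) -> pd.DatetimeIndex:
    """UTC+9 calendar dates (normalized, tz-naive) of tz-aware timestamps."""
    t = pd.DatetimeIndex(timestamps)
    return t.tz_convert(KST_NAME).tz_localize(None).normalize()
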
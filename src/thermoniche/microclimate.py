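"""Day/night summaries of fixed-interval ground-temperature logs.

A logger records temperature every few minutes (5 min in the field design)
for a run of continuous days.  Samples are partitioned by local clock time
into a day window (default [7:00, 18:00)) and its complement, and the mean,
maximum and minimum of each partition are reported together with the
**thermal amplitude** = day maximum - night minimum.  By default the extremes
are taken over the whole record; a per-day variant (daily extremes averaged
across days) is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DielSummary", "summarize_log", "DEFAULT_DAY_WINDOW"]

DEFAULT_DAY_WINDOW = (7.0, 18.0)


@dataclass(frozen=True)
class DielSummary:
    day_mean: float
    day_max: float
    day_min: float
    night_mean: float
    night_max: float
    night_min: float

    @property
    def amplitude(self) -> float:
        """Thermal amplitude: day maximum minus night minimum."""
        return self.day_max - self.night_min

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in
             ("day_mean", "day_max", "day_min",
              "night_mean", "night_max", "night_min")}
        d["amplitude"] = self.amplitude
        return d


def summarize_log(log: pd.DataFrame,
                  day_window: tuple[float, float] = DEFAULT_DAY_WINDOW,
                  per_day: bool = False) -> DielSummary:
    """Summarize a sensor log into day/night statistics.

    ``log`` needs ``timestamp`` and ``temp_c`` columns.  The day window is
    half-open [start, end) in local clock hours.  With ``per_day=True`` the
    six statistics are computed per calendar day and averaged, so the
    amplitude becomes mean(daily day max) - mean(daily night min).
    """
    if log.empty:
        raise ValueError("empty sensor log")
    ts = pd.to_datetime(log["timestamp"])
    temps = log["temp_c"].to_numpy(dtype=float)
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    b0, b1 = day_window
    day = ((hours >= b0) & (hours < b1)).to_numpy()
    if not day.any() or day.all():
        raise ValueError("day or night partition is empty")

    if not per_day:
        return DielSummary(
            day_mean=float(temps[day].mean()), day_max=float(temps[day].max()),
            day_min=float(temps[day].min()),
            night_mean=float(temps[~day].mean()),
            night_max=float(temps[~day].max()),
            night_min=float(temps[~day].min()))

    df = pd.DataFrame({"date": ts.dt.date, "temp": temps, "day": day})
    parts = {}
    for is_day, label in ((True, "day"), (False, "night")):
        sub = df[df["day"] == is_day]
        grouped = sub.groupby("date")["temp"]
        parts[f"{label}_mean"] = float(grouped.mean().mean())
        parts[f"{label}_max"] = float(grouped.max().mean())
        parts[f"{label}_min"] = float(grouped.min().mean())
    return DielSummary(**parts)
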
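"""Colony-attendance phenology from geolocator immersion and light data.

Leg-mounted geolocators record saltwater immersion (wet/dry, tested every
3 s) and light.  Depending on the logger model the immersion record is
stored either as state-change events or as the number of positive (wet)
tests out of 200 per 10-minute period.  Both dialects are normalized to a
wet fraction per 10-minute bin.  Because the loggers are leg-mounted and
the birds only attend the colony at night (except when in the burrow),
colony visits show up as unusually long *dry* periods at night -- longer
than the longest continuous flight -- and incubation stints as whole days
that are dry with the light record dark or heavily obscured during
daylight (bird underground).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ActivityTrace",
    "ColonyVisit",
    "normalize_activity",
    "classify_colony_visits",
    "night_mask_from_hours",
    "night_mask_from_light",
    "first_arrival",
    "incubation_bouts",
    "read_activity_tsv",
    "write_activity_tsv",
]

BIN = pd.Timedelta(minutes=10)
LIGHT_BIN = pd.Timedelta(minutes=5)


@dataclass
class ActivityTrace:
    """Normalized logger record for one bird.

    ``wet`` is a Series of wet fractions in [0, 1] on a gap-free 10-minute
    grid (index = bin start); ``light`` is the maximum light per 5-minute
    bin (may be None when only immersion was recorded).
    """

    bird_id: str
    wet: pd.Series
    light: pd.Series | None = None

    def __post_init__(self):
        idx = self.wet.index
        if len(idx) > 1:
            deltas = np.unique(np.diff(idx.asi8))
            if len(deltas) != 1 or deltas[0] != BIN.value:
                raise ValueError("wet grid must be gap-free at 10-minute spacing")
        w = self.wet.to_numpy(dtype=float)
        if ((w < -1e-9) | (w > 1 + 1e-9)).any():
            raise ValueError("wet fractions must lie in [0, 1]")
        if self.light is not None and len(self.light.index) > 1:
            deltas = np.unique(np.diff(self.light.index.asi8))
            if len(deltas) != 1 or deltas[0] != LIGHT_BIN.value:
                raise ValueError("light grid must be gap-free at 5-minute spacing")

    @property
    def start(self) -> pd.Timestamp:
        return self.wet.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.wet.index[-1] + BIN


@dataclass
class ColonyVisit:
    """One colony attendance: a night visit or a run including burrow days."""

    bird_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    kind: str  # "night-visit" | "burrow-day"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("visit end must be after start")
        if self.kind not in ("night-visit", "burrow-day"):
            raise ValueError(f"unknown visit kind {self.kind!r}")

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start

    def dates(self) -> list:
        """Calendar dates touched by this visit."""
        return list(
            pd.date_range(self.start.normalize(),
                          (self.end - pd.Timedelta(seconds=1)).normalize()).date
        )


# ---------------------------------------------------------------------------
# Normalization

def normalize_activity(
    raw: pd.DataFrame,
    dialect: str,
    bird_id: str = "",
    light: pd.Series | None = None,
    period: tuple | None = None,
) -> ActivityTrace:
    """Normalize a raw immersion record to a wet-fraction trace.

    Parameters
    ----------
    raw
        ``counts-0-200`` dialect: columns ``timestamp`` (start of each
        10-minute period) and ``value`` (number of positive 3-s wet tests,
        0..200).  ``state-change`` dialect: columns ``timestamp`` and
        ``state`` ("wet"/"dry"), each row marking the instant the state
        begins; the state persists until the next event.
    period
        (start, end) of the deployment for the state-change dialect;
        defaults to the span of the events.
    """
    if dialect == "counts-0-200":
        ts = pd.DatetimeIndex(raw["timestamp"])
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be non-decreasing")
        vals = raw["value"].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 200)).any():
            raise ValueError("counts must lie in 0..200")
        wet = pd.Series(vals / 200.0, index=ts)
    elif dialect == "state-change":
        wet = _integrate_state_changes(raw, period)
    else:
        raise ValueError(f"unknown logger dialect {dialect!r}")
    return ActivityTrace(bird_id=bird_id, wet=wet, light=light)


def _integrate_state_changes(raw: pd.DataFrame, period) -> pd.Series:
    ts = pd.DatetimeIndex(raw["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be non-decreasing")
    states = [str(s).lower() for s in raw["state"]]
    if not set(states) <= {"wet", "dry"}:
        raise ValueError("states must be 'wet' or 'dry'")
    if period is None:
        start, end = ts[0].floor("10min"), ts[-1].ceil("10min")
    else:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    bins = pd.date_range(start, end, freq="10min", inclusive="left")
    wet_seconds = np.zeros(len(bins))
    # state before the first event is the opposite of the first event's state
    events = list(zip(ts, states))
    segs = []
    cur_state = "dry" if events and events[0][1] == "wet" else "wet"
    cur_start = start
    for t, s in events:
        if t > cur_start:
            segs.append((cur_start, min(t, end), cur_state))
        cur_start = max(t, cur_start)
        cur_state = s
    if cur_start < end:
        segs.append((cur_start, end, cur_state))
    bin_ns = BIN.value
    t0 = bins[0].value
    for s, e, state in segs:
        if state != "wet" or e <= s:
            continue
        i0 = max(int((s.value - t0) // bin_ns), 0)
        i1 = min(int((e.value - t0 - 1) // bin_ns), len(bins) - 1)
        for i in range(i0, i1 + 1):
            lo = max(s.value, t0 + i * bin_ns)
            hi = min(e.value, t0 + (i + 1) * bin_ns)
            wet_seconds[i] += max(hi - lo, 0) / 1e9
    return pd.Series(wet_seconds / 600.0, index=bins).clip(0, 1)


# ---------------------------------------------------------------------------
# Night masks

def night_mask_from_hours(index: pd.DatetimeIndex, night_start: int = 19,
                          night_end: int = 7) -> np.ndarray:
    """Clock-hour night mask (default 19:00-07:00) aligned to a bin grid."""
    h = index.hour
    if night_start > night_end:
        return (h >= night_start) | (h < night_end)
    return (h >= night_start) & (h < night_end)


def night_mask_from_light(trace: ActivityTrace, darkness_threshold: float = 5.0,
                          min_dark_hours: float = 6.0) -> np.ndarray:
    """Night mask on the 10-minute grid from the light record.

    A bin is dark when the maximum light of its two 5-minute light bins is
    below ``darkness_threshold``.  Because a bird in its burrow is also
    dark by day, only dark runs longer than ``min_dark_hours`` that recur
    at the same clock time are truly night; this simple version marks a
    10-minute bin as night when it is dark on the majority of days at that
    clock time, which is robust to occasional burrow days.
    """
    if trace.light is None:
        raise ValueError("trace has no light record")
    dark10 = _light_to_10min(trace) < darkness_threshold
    idx = trace.wet.index
    tod = idx.hour * 6 + idx.minute // 10  # 10-min slot of day
    night_slots = np.zeros(144, dtype=bool)
    for slot in range(144):
        sel = tod == slot
        if sel.any():
            night_slots[slot] = dark10[sel].mean() > 0.5
    return night_slots[tod]


def _light_to_10min(trace: ActivityTrace) -> np.ndarray:
    """Max light per 10-minute wet bin (pairs of 5-minute light bins)."""
    light = trace.light.reindex(
        pd.date_range(trace.start, trace.end, freq="5min", inclusive="left")
    )
    arr = light.to_numpy(dtype=float)
    return np.fmax(arr[0::2], arr[1::2])


# ---------------------------------------------------------------------------
# Visit classification

def classify_colony_visits(
    trace: ActivityTrace,
    night_mask: np.ndarray,
    dry_threshold_hours: float = 4.0,
    darkness_threshold: float = 5.0,
    burrow_day_dark_fraction: float = 0.8,
    max_wet_fraction: float = 0.0,
) -> list[ColonyVisit]:
    """Detect colony visits as long nocturnal dry spells and burrow days.

    A maximal run of fully dry night bins strictly longer than
    ``dry_threshold_hours`` becomes a night visit.  A calendar day whose
    daylight bins are dark (below ``darkness_threshold``) for at least
    ``burrow_day_dark_fraction`` of the day while the immersion record
    stays dry becomes a burrow day.  Adjacent night-visit and burrow-day
    segments merge into a single visit (kind "burrow-day" when any burrow
    day is included).  ``max_wet_fraction > 0`` enables the permissive
    mode in which brief wet ticks within a bin do not break a dry run.
    """
    if dry_threshold_hours <= 0:
        raise ValueError("dry threshold must be positive")
    night_mask = np.asarray(night_mask, dtype=bool)
    if len(night_mask) != len(trace.wet):
        raise ValueError("night mask must align with the 10-minute grid")

    idx = trace.wet.index
    dry = trace.wet.to_numpy(dtype=float) <= max_wet_fraction
    min_bins = int(np.floor(dry_threshold_hours * 6)) + 1  # strictly longer

    intervals = []  # (start, end, is_burrow)
    for i0, i1 in _runs(dry & night_mask):
        if i1 - i0 >= min_bins:
            intervals.append((idx[i0], idx[i1 - 1] + BIN, False))

    if trace.light is not None:
        dark10 = _light_to_10min(trace) < darkness_threshold
        for date in np.unique(idx.normalize()):
            day_sel = (idx.normalize() == date) & ~night_mask
            if not day_sel.any():
                continue
            all_dry = dry[idx.normalize() == date].all()
            if all_dry and dark10[day_sel].mean() >= burrow_day_dark_fraction:
                d = pd.Timestamp(date)
                intervals.append((d, d + pd.Timedelta(days=1), True))

    merged = _merge_intervals(intervals)
    return [
        ColonyVisit(trace.bird_id, s, e, "burrow-day" if b else "night-visit")
        for s, e, b in merged
    ]


def _runs(mask: np.ndarray):
    """Maximal [i0, i1) runs of True."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _merge_intervals(intervals):
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e, b in ivs[1:]:
        if s <= merged[-1][1]:  # adjacent or overlapping
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = merged[-1][2] or b
        else:
            merged.append([s, e, b])
    return [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# Phenology summaries

def first_arrival(visits_by_bird: dict, season_start) -> pd.DataFrame:
    """First colony visit per bird after a season start, with mean +- SD.

    Returns a frame (bird -> first visit timestamp and day offset) with
    ``attrs`` holding ``mean_date``, ``sd_days`` and ``n``.  Birds without
    a qualifying visit are excluded with a warning.
    """
    import warnings

    season_start = pd.Timestamp(season_start)
    rows = {}
    for bird, visits in visits_by_bird.items():
        starts = [v.start for v in visits if v.start >= season_start]
        if not starts:
            warnings.warn(f"bird {bird}: no visits after {season_start.date()}")
            continue
        first = min(starts)
        rows[bird] = {
            "first_visit": first,
            "day_offset": (first - season_start) / pd.Timedelta(days=1),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if len(df):
        offs = df["day_offset"].to_numpy()
        df.attrs["mean_date"] = season_start + pd.Timedelta(days=float(offs.mean()))
        df.attrs["sd_days"] = float(offs.std(ddof=1)) if len(offs) > 1 else 0.0
        df.attrs["n"] = int(len(offs))
    return df


def incubation_bouts(visits: list, window: tuple) -> pd.DataFrame:
    """Incubation bout durations from burrow-day runs inside a window.

    Maximal runs of consecutive burrow days form bouts; durations are in
    whole days.  Returns a frame of bouts with ``attrs`` ``mean_days`` /
    ``sd_days``.
    """
    w0, w1 = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    days = set()
    for v in visits:
        if v.kind != "burrow-day":
            continue
        for d in v.dates():
            d = pd.Timestamp(d)
            if w0 <= d <= w1:
                days.add(d)
    bouts = []
    for d0, d1 in _date_runs(sorted(days)):
        bouts.append({"start": d0, "end": d1, "days": (d1 - d0).days + 1})
    df = pd.DataFrame(bouts)
    if len(df):
        dur = df["days"].to_numpy(dtype=float)
        df.attrs["mean_days"] = float(dur.mean())
        df.attrs["sd_days"] = float(dur.std(ddof=1)) if len(dur) > 1 else 0.0
    return df


def _date_runs(days):
    runs = []
    for d in days:
        if runs and (d - runs[-1][1]).days == 1:
            runs[-1][1] = d
        else:
            runs.append([d, d])
    return [tuple(r) for r in runs]


# ---------------------------------------------------------------------------
# Tab-separated I/O (timestamp + value per line, one file per bird/sensor)

def write_activity_tsv(series: pd.Series, path) -> None:
    with open(path, "w") as fh:
        for t, v in series.items():
            fh.write(f"{t.isoformat()}\t{v:g}\n")


def read_activity_tsv(path) -> pd.Series:
    ts, vals = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            t, v = line.rstrip("\n").split("\t")
            ts.append(pd.Timestamp(t))
            vals.append(float(v))
    return pd.Series(vals, index=pd.DatetimeIndex(ts))
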
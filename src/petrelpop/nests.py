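"""Nest-monitoring outcomes and annual breeding success.

The species lays a single egg per season with no replacement clutch, so a
season's outcome for a burrow is one of a small taxonomy:

* ``successful`` -- a chick was present during the fledging period (or
  fledging was observed directly);
* ``chick-lost`` -- a chick was seen but disappeared before the fledging
  period;
* ``egg-lost`` -- an egg was confirmed but no chick ever was (broken,
  abandoned or disappeared);
* ``adult-killed`` -- an incubating adult was killed (egg confirmed);
* ``no-egg`` -- an adult attended the burrow but never had an egg;
* ``empty`` -- neither adult nor egg was found;
* ``active-not-confirmed`` -- attendance evidence only (or the nest was
  inaccessible), so breeding could not be confirmed.

Annual breeding success is fledged nests over confirmed-active nests
(those with an egg or chick confirmed: successful, chick-lost, egg-lost,
adult-killed); inaccessible/unconfirmed nests stay out of the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NestVisit",
    "NestRecord",
    "SeasonOutcome",
    "season_outcomes",
    "summarize_statuses",
    "read_nest_csv",
    "write_nest_csv",
    "STATUSES",
    "ACTIVE_STATUSES",
]

STATUSES = [
    "successful",
    "chick-lost",
    "egg-lost",
    "adult-killed",
    "no-egg",
    "empty",
    "active-not-confirmed",
]

#: Statuses with a confirmed breeding attempt (an egg or chick was seen).
ACTIVE_STATUSES = {"successful", "chick-lost", "egg-lost", "adult-killed"}


@dataclass
class NestVisit:
    date: pd.Timestamp
    adult: bool = False
    egg: bool = False
    chick: bool = False
    fledged: bool = False
    evidence: str = ""  # "", "attendance", "predation", "harvest", "adult-killed"
    inaccessible: bool = False

    def __post_init__(self):
        self.date = pd.Timestamp(self.date)


@dataclass
class NestRecord:
    """Dated visit observations for one burrow in one breeding season."""

    nest_id: str
    season: str  # e.g. "2014/2015"
    visits: list = field(default_factory=list)

    def __post_init__(self):
        self.visits = sorted(self.visits, key=lambda v: v.date)
        y0, y1 = self.season_years
        lo = pd.Timestamp(year=y0, month=8, day=1)
        hi = pd.Timestamp(year=y1, month=7, day=31)
        for v in self.visits:
            if not lo <= v.date <= hi:
                raise ValueError(
                    f"nest {self.nest_id}: visit {v.date.date()} outside "
                    f"season {self.season}"
                )
        egg_dates = [v.date for v in self.visits if v.egg]
        chick_dates = [v.date for v in self.visits if v.chick or v.fledged]
        if egg_dates and chick_dates and min(chick_dates) < min(egg_dates):
            raise ValueError(
                f"nest {self.nest_id}: chick/fledging observed before the egg"
            )

    @property
    def season_years(self) -> tuple:
        a, b = self.season.split("/")
        return int(a), int(b)


@dataclass
class SeasonOutcome:
    nest_id: str
    season: str
    status: str
    fledge_date: pd.Timestamp | None = None


def season_outcomes(
    records: list,
    fledging_start: str = "05-01",
) -> tuple[list, pd.DataFrame]:
    """Derive per-nest season outcomes and the annual summary.

    ``fledging_start`` (month-day within the closing calendar year of the
    season) marks the start of the fledging period: a chick seen on or
    after it, or an explicit fledged observation, makes the season
    successful; a chick that disappears before it is ``chick-lost``.
    """
    outcomes = []
    for rec in records:
        outcomes.append(_derive(rec, fledging_start))
    by_season = {}
    for o in outcomes:
        by_season.setdefault(o.season, []).append(o.status)
    summary = summarize_statuses(by_season)
    return outcomes, summary


def _derive(rec: NestRecord, fledging_start: str) -> SeasonOutcome:
    _, y1 = rec.season_years
    fledge_window = pd.Timestamp(f"{y1}-{fledging_start}")
    saw_adult = any(v.adult for v in rec.visits)
    saw_egg = any(v.egg for v in rec.visits)
    chick_dates = [v.date for v in rec.visits if v.chick]
    fledged_obs = [v.date for v in rec.visits if v.fledged]
    inaccessible = any(v.inaccessible for v in rec.visits)
    attendance = any(v.evidence == "attendance" for v in rec.visits)
    adult_killed = any(
        v.evidence in ("adult-killed", "harvest", "predation") and not v.chick
        for v in rec.visits
    )

    status: str
    fledge_date = None
    if fledged_obs or any(d >= fledge_window for d in chick_dates):
        status = "successful"
        candidates = fledged_obs + [d for d in chick_dates if d >= fledge_window]
        fledge_date = max(candidates)
    elif chick_dates:
        status = "chick-lost"
    elif saw_egg:
        status = "adult-killed" if adult_killed else "egg-lost"
    elif inaccessible and (saw_adult or attendance):
        status = "active-not-confirmed"
    elif saw_adult:
        status = "no-egg"
    elif attendance:
        status = "active-not-confirmed"
    else:
        status = "empty"
    return SeasonOutcome(rec.nest_id, rec.season, status, fledge_date)


def summarize_statuses(statuses_by_season: dict) -> pd.DataFrame:
    """Annual summary from per-nest statuses.

    Returns a frame indexed by season with confirmed-active nest count,
    fledgling count and breeding success in whole percent (NaN when no
    nest was confirmed active).
    """
    rows = {}
    for season in sorted(statuses_by_season):
        statuses = [s for s in statuses_by_season[season] if s != "unknown"]
        bad = set(statuses) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown statuses {sorted(bad)}")
        active = sum(s in ACTIVE_STATUSES for s in statuses)
        fledged = sum(s == "successful" for s in statuses)
        pct = round(100.0 * fledged / active) if active else np.nan
        rows[season] = {"active": active, "fledged": fledged, "success_pct": pct}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "season"
    return df


# ---------------------------------------------------------------------------
# CSV log: nest,season,date,adult,egg,chick,fledged,evidence[,inaccessible]

def write_nest_csv(records: list, path) -> None:
    rows = []
    for rec in records:
        for v in rec.visits:
            rows.append(
                {
                    "nest": rec.nest_id,
                    "season": rec.season,
                    "date": v.date.date().isoformat(),
                    "adult": int(v.adult),
                    "egg": int(v.egg),
                    "chick": int(v.chick),
                    "fledged": int(v.fledged),
                    "evidence": v.evidence,
                    "inaccessible": int(v.inaccessible),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nest_csv(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    records = {}
    for _, row in df.iterrows():
        key = (str(row["nest"]), str(row["season"]))
        records.setdefault(key, []).append(
            NestVisit(
                date=row["date"],
                adult=bool(int(row["adult"])),
                egg=bool(int(row["egg"])),
                chick=bool(int(row["chick"])),
                fledged=bool(int(row["fledged"])),
                evidence=str(row["evidence"]),
                inaccessible=bool(int(row.get("inaccessible", 0))),
            )
        )
    return [
        NestRecord(nest_id=k[0], season=k[1], visits=v) for k, v in records.items()
    ]
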
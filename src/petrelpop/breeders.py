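"""Brood-patch based enumeration of possible breeders.

Incubating petrels develop a bare, vascularised brood patch; its stage is
scored 0 (no defeathering) through 4 (refeathering), with 99 for birds not
examined.  Comparing scores of mist-netted birds with those of birds
captured on the nest in the same season gives three graded counts of
possible breeders among the mist-netted sample:

* ``min`` -- only birds with a fully developed patch (score 2);
* ``probable`` -- score-2 birds plus birds whose score matches any score
  (excluding 99) seen among that year's nest-captured (known) breeders;
* ``max`` -- every bird except those unscored (99) or with no
  defeathering at all (score 0).

Percentages use the full mist-net yearly total (all scores, including 99)
as denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SCORES = [99, 0, 1, 2, 3, 4]

__all__ = ["BroodPatchYear", "BroodPatchTable", "breeder_counts", "breeder_population"]


@dataclass
class BroodPatchYear:
    """Score counts for one year at one capture location."""

    year: int
    location: str  # "nest" | "mist-net"
    counts: dict
    date_range: str = ""

    def __post_init__(self):
        if self.location not in ("nest", "mist-net"):
            raise ValueError(f"unknown capture location {self.location!r}")
        bad = set(self.counts) - set(SCORES)
        if bad:
            raise ValueError(f"unknown brood patch scores {sorted(bad)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("score counts must be non-negative")
        self.counts = {s: int(self.counts.get(s, 0)) for s in SCORES}

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class BroodPatchTable:
    rows: list

    def location_years(self, location: str) -> dict:
        return {r.year: r for r in self.rows if r.location == location}


def breeder_counts(table: BroodPatchTable, mode: str = "probable") -> pd.DataFrame:
    """Count possible breeders among mist-netted birds, by year.

    Returns a frame indexed by year with columns ``count``, ``total`` and
    ``percent`` (unrounded) plus attrs ``mean_count`` / ``mean_percent``,
    the arithmetic means over years with nest data.  For ``probable``,
    years without any scored nest bird are skipped with a warning.
    """
    if mode not in ("min", "probable", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    mist = table.location_years("mist-net")
    nest = table.location_years("nest")

    records = {}
    for year, row in sorted(mist.items()):
        c = row.counts
        total = row.total
        if mode == "min":
            count = c[2]
        elif mode == "max":
            count = total - c[99] - c[0]
        else:
            nest_row = nest.get(year)
            nest_scores = (
                {s for s in (0, 1, 2, 3, 4) if nest_row.counts[s] > 0}
                if nest_row is not None
                else set()
            )
            if not nest_scores:
                warnings.warn(
                    f"{year}: no scored nest-captured birds; year skipped for "
                    "mode='probable'"
                )
                continue
            count = sum(c[s] for s in nest_scores | {2})
        pct = 100.0 * count / total if total else 0.0
        records[year] = (count, total, pct)

    df = pd.DataFrame.from_dict(
        records, orient="index", columns=["count", "total", "percent"]
    )
    df.index.name = "year"
    # across-year means are taken over the years with nest data
    mean_years = [y for y in records if y in nest]
    sub = df.loc[mean_years] if mean_years else df
    df.attrs["mean_count"] = float(sub["count"].mean()) if len(sub) else float("nan")
    df.attrs["mean_percent"] = float(sub["percent"].mean()) if len(sub) else float("nan")
    return df


def breeder_population(n_hat: float, ci: tuple, proportion: float):
    """Scale a super-population estimate and CI by a breeder proportion.

    ``proportion`` is a fraction in [0, 1] (the rounded mean breeder
    percentage / 100).  Counts round to the nearest bird.
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    lo, hi = ci
    point = int(np.rint(proportion * n_hat))
    return point, (int(np.rint(proportion * lo)), int(np.rint(proportion * hi)))
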
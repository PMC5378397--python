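"""Synthetic-data generators with known ground truth for every input stream.

Each generator emulates one field data stream of a long-term petrel
monitoring programme -- encounter histories from an open population,
per-sex biometric samples, geolocator immersion/light traces with scripted
colony visits, nest visit logs, and two-group isotope-like samples -- and
returns the latent truth alongside the observables so every downstream
analysis can be tested without real data.

Defaults are the study's published point estimates (super-population 293,
apparent survival 0.76, entry probability 0.07 per interval, capture
probabilities in the printed range; per-sex trait means and SDs; the
nest-outcome frequencies of the monitored burrows; the published isotope
group summaries), so a "study-like" simulation needs no configuration.
Trait correlations are not published; traits are independent by default.
All randomness flows from a mandatory integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .capture import EncounterHistoryTable
from .phenology import ActivityTrace, ColonyVisit
from .nests import NestRecord, NestVisit, STATUSES

__all__ = [
    "PopanSimConfig",
    "BiometricsSimConfig",
    "ActivitySimConfig",
    "NestsSimConfig",
    "TwoGroupSimConfig",
    "SimulationConfig",
    "gen_popan_histories",
    "gen_biometrics",
    "gen_activity",
    "gen_nests",
    "gen_two_group_samples",
]


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("a seed is mandatory for any stochastic call")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration blocks

@dataclass
class PopanSimConfig:
    N: int = 293
    T: int = 10
    phi: float | list = 0.76
    pent: float | list = 0.07  # shared entry per interval; beta_0 by subtraction
    p: float | list = 0.25

    def vectors(self):
        T = self.T
        phi = np.broadcast_to(np.atleast_1d(self.phi), (T - 1,)).astype(float)
        p = np.broadcast_to(np.atleast_1d(self.p), (T,)).astype(float)
        pent = np.atleast_1d(self.pent).astype(float)
        if pent.size == 1:
            beta = np.r_[1 - (T - 1) * pent[0], np.full(T - 1, pent[0])]
        elif pent.size == T:
            beta = pent
        else:
            raise ValueError("pent must be scalar or length T")
        if not np.isclose(beta.sum(), 1.0):
            raise ValueError("entry probabilities must sum to 1")
        if ((beta < 0) | (beta > 1)).any() or ((phi < 0) | (phi > 1)).any() \
                or ((p < 0) | (p > 1)).any():
            raise ValueError("all probabilities must lie in [0, 1]")
        return phi, p, beta


@dataclass
class BiometricsSimConfig:
    """Per-sex multivariate-normal biometrics (defaults: published summaries)."""

    n_male: int = 49
    n_female: int = 72
    male_mean: list = None  # type: ignore[assignment]
    male_sd: list = None  # type: ignore[assignment]
    female_mean: list = None  # type: ignore[assignment]
    female_sd: list = None  # type: ignore[assignment]
    correlation: list | None = None  # optional common trait correlation matrix

    def __post_init__(self):
        from . import datasets

        for sex in ("male", "female"):
            m, s = datasets.biometrics_mvn_params(sex)
            if getattr(self, f"{sex}_mean") is None:
                setattr(self, f"{sex}_mean", list(m))
            if getattr(self, f"{sex}_sd") is None:
                setattr(self, f"{sex}_sd", list(s))


@dataclass
class ActivitySimConfig:
    n_birds: int = 7
    season_start: str = "2013-08-01"
    season_end: str = "2013-11-30"
    arrival_mean_doy: int = 267  # 24 September
    arrival_sd_days: float = 12.0
    visit_min_hours: float = 4.5
    visit_max_hours: float = 8.0
    visit_interval_nights: int = 3
    dry_noise_rate: float = 0.0  # P(an at-sea bin is fully dry): short flights
    scripted_visits: dict | None = None  # bird -> list of (start, hours) night visits
    scripted_bouts: dict | None = None  # bird -> list of (start_date, n_days)
    night_start_hour: int = 19
    night_end_hour: int = 7
    day_light: float = 200.0


@dataclass
class NestsSimConfig:
    n_nests: int = 14
    season: str = "2014/2015"
    #: Status probabilities; defaults are the empirical frequencies of the
    #: monitored burrows across the four published seasons.
    outcome_probs: dict = field(
        default_factory=lambda: {
            "successful": 20 / 49,
            "empty": 12 / 49,
            "no-egg": 6 / 49,
            "egg-lost": 4 / 49,
            "active-not-confirmed": 4 / 49,
            "chick-lost": 2 / 49,
            "adult-killed": 1 / 49,
        }
    )


@dataclass
class TwoGroupSimConfig:
    mean1: float = 8.19
    sd1: float = 0.32
    n1: int = 10
    mean2: float = 7.37
    sd2: float = 0.60
    n2: int = 8


@dataclass
class SimulationConfig:
    seed: int = 0
    popan: PopanSimConfig = field(default_factory=PopanSimConfig)
    biometrics: BiometricsSimConfig = field(default_factory=BiometricsSimConfig)
    activity: ActivitySimConfig = field(default_factory=ActivitySimConfig)
    nests: NestsSimConfig = field(default_factory=NestsSimConfig)
    two_group: TwoGroupSimConfig = field(default_factory=TwoGroupSimConfig)

    def to_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# Encounter histories

def gen_popan_histories(
    config: PopanSimConfig, seed: int
) -> tuple[EncounterHistoryTable | None, pd.DataFrame]:
    """Simulate individual encounter histories from the entry/survival/
    capture process.

    Each of ``N`` super-population individuals draws an entry occasion
    from the entry vector, survives each following interval with
    probability ``phi`` and, while present, is detected with probability
    ``p``.  Returns the table of ever-detected histories (``None`` when no
    individual was detected) and the full latent record (entry occasion,
    last occasion alive, detection matrix row index).
    """
    rng = _rng(seed)
    phi, p, beta = config.vectors()
    T = config.T
    N = int(config.N)

    entry = rng.choice(T, size=N, p=beta)
    alive = np.zeros((N, T), dtype=bool)
    last_alive = np.empty(N, dtype=int)
    for i in range(N):
        e = entry[i]
        alive[i, e] = True
        t = e
        while t + 1 < T and rng.random() < phi[t]:
            t += 1
            alive[i, t] = True
        last_alive[i] = t
    detected = alive & (rng.random((N, T)) < p)

    latent = pd.DataFrame(
        {
            "entry": entry + 1,
            "last_alive": last_alive + 1,
            "ever_detected": detected.any(axis=1),
        }
    )
    obs = detected[detected.any(axis=1)]
    if len(obs) == 0:
        return None, latent
    table = EncounterHistoryTable(
        occasions=list(range(1, T + 1)), histories=obs.astype(int)
    )
    return table, latent


# ---------------------------------------------------------------------------
# Biometrics

def gen_biometrics(config: BiometricsSimConfig, seed: int) -> pd.DataFrame:
    """Per-sex multivariate-normal biometric draws with field quantization.

    Wing length is quantized to 0.5 mm (ruler), all other traits to
    0.01 mm (caliper).  Returns one row per bird with the true sex.
    """
    from .biometrics import TRAITS

    rng = _rng(seed)
    rows = []
    for sex, n, mean, sd in (
        ("male", config.n_male, config.male_mean, config.male_sd),
        ("female", config.n_female, config.female_mean, config.female_sd),
    ):
        mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        if config.correlation is not None:
            corr = np.asarray(config.correlation, dtype=float)
            cov = corr * np.outer(sd, sd)
            if np.linalg.eigvalsh(cov).min() < -1e-10:
                raise ValueError("correlation matrix is not positive-definite")
            draws = rng.multivariate_normal(mean, cov, size=n, method="eigh")
        else:
            draws = mean + sd * rng.standard_normal((n, len(mean)))
        for k, x in enumerate(draws):
            x = x.copy()
            for j, t in enumerate(TRAITS):
                step = 0.5 if t == "wing" else 0.01
                x[j] = np.round(x[j] / step) * step
            rows.append({"id": f"{sex[0]}{k + 1}", "sex": sex,
                         **dict(zip(TRAITS, x))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Geolocator activity

def gen_activity(
    config: ActivitySimConfig, seed: int
) -> tuple[dict, dict]:
    """Simulate immersion/light traces with scripted or drawn colony visits.

    The at-sea baseline is wet-dominated (every 10-minute bin has positive
    wet fraction) with optional brief dry flight bins at
    ``dry_noise_rate``.  Night visits are fully dry runs longer than the
    detection threshold; incubation bouts are whole days dry with the
    daylight light record dark.  Returns ``(traces, truth)`` keyed by bird
    id, where truth is the list of injected :class:`ColonyVisit`.
    """
    rng = _rng(seed)
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end)
    if end <= start:
        raise ValueError("season end must be after start")
    bins = pd.date_range(start, end, freq="10min", inclusive="left")
    light_bins = pd.date_range(start, end, freq="5min", inclusive="left")
    n_bins = len(bins)
    year = start.year

    traces, truth = {}, {}
    for b in range(config.n_birds):
        bird = f"bird{b + 1}"
        wet = rng.uniform(0.2, 1.0, n_bins)
        if config.dry_noise_rate > 0:
            wet[rng.random(n_bins) < config.dry_noise_rate] = 0.0
        hours = light_bins.hour
        day = (hours >= config.night_end_hour) & (hours < config.night_start_hour)
        light = np.where(day, config.day_light, 0.0)

        visits: list[ColonyVisit] = []
        if config.scripted_visits is not None:
            night_plan = config.scripted_visits.get(bird, [])
        else:
            night_plan = _draw_night_visits(config, rng, year)
        for vstart, vhours in night_plan:
            vstart = pd.Timestamp(vstart)
            vend = vstart + pd.Timedelta(hours=float(vhours))
            if vstart < start or vend > end:
                raise ValueError(
                    f"scripted visit {vstart} outside the deployment window"
                )
            visits.append(ColonyVisit(bird, vstart, vend, "night-visit"))

        bout_plan = (config.scripted_bouts or {}).get(bird, [])
        for d0, n_days in bout_plan:
            d0 = pd.Timestamp(d0)
            d1 = d0 + pd.Timedelta(days=int(n_days))
            if d0 < start or d1 > end:
                raise ValueError(f"scripted bout {d0.date()} outside deployment")
            visits.append(ColonyVisit(bird, d0, d1, "burrow-day"))

        for v in visits:
            sel = (bins >= v.start) & (bins < v.end)
            wet[sel] = 0.0
            if v.kind == "burrow-day":
                lsel = (light_bins >= v.start) & (light_bins < v.end)
                light[lsel] = 0.0

        traces[bird] = ActivityTrace(
            bird_id=bird,
            wet=pd.Series(wet, index=bins),
            light=pd.Series(light, index=light_bins),
        )
        truth[bird] = sorted(visits, key=lambda v: v.start)
    return traces, truth


def _draw_night_visits(config: ActivitySimConfig, rng, year):
    """Arrival date ~ Normal(mean doy, sd); visits every few nights after."""
    arrival_doy = rng.normal(config.arrival_mean_doy, config.arrival_sd_days)
    arrival = pd.Timestamp(f"{year}-01-01") + pd.Timedelta(
        days=float(np.round(arrival_doy)) - 1
    )
    start = pd.Timestamp(config.season_start)
    end = pd.Timestamp(config.season_end)
    arrival = max(arrival, start + pd.Timedelta(days=1))
    plan = []
    d = arrival
    while d < end - pd.Timedelta(days=1):
        # durations quantized to the 10-minute logger grid
        vhours = round(
            rng.uniform(config.visit_min_hours, config.visit_max_hours) * 6
        ) / 6
        # start the visit early in the night so it ends before dawn
        t0 = d.normalize() + pd.Timedelta(hours=config.night_start_hour + 1)
        if t0 + pd.Timedelta(hours=vhours) < end:
            plan.append((t0, vhours))
        d += pd.Timedelta(days=int(rng.integers(1, config.visit_interval_nights + 2)))
    return plan


# ---------------------------------------------------------------------------
# Nests

def gen_nests(
    config: NestsSimConfig, seed: int
) -> tuple[list, dict]:
    """Draw per-nest season outcomes and emit consistent dated visit logs.

    Returns ``(records, truth)`` where truth maps nest id to the drawn
    status.  Emitted logs always satisfy nest-record validation.
    """
    rng = _rng(seed)
    probs = config.outcome_probs
    bad = set(probs) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown outcome statuses {sorted(bad)}")
    p = np.array(list(probs.values()), dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("outcome probabilities must sum to 1")
    names = list(probs)

    y0, y1 = (int(x) for x in config.season.split("/"))
    lay = pd.Timestamp(f"{y1}-01-20")
    hatch = pd.Timestamp(f"{y1}-03-10")
    fledge = pd.Timestamp(f"{y1}-05-20")

    records, truth = [], {}
    for k in range(config.n_nests):
        nest = f"nest{k + 1}"
        status = names[rng.choice(len(p), p=p)]
        truth[nest] = status
        jitter = pd.Timedelta(days=int(rng.integers(0, 8)))
        visits = []
        if status == "empty":
            visits = [NestVisit(lay + jitter)]
        elif status == "no-egg":
            visits = [NestVisit(lay + jitter, adult=True)]
        elif status == "active-not-confirmed":
            visits = [
                NestVisit(lay + jitter, evidence="attendance", inaccessible=True)
            ]
        elif status == "egg-lost":
            visits = [NestVisit(lay + jitter, adult=True, egg=True),
                      NestVisit(hatch + jitter)]
        elif status == "adult-killed":
            visits = [NestVisit(lay + jitter, adult=True, egg=True),
                      NestVisit(lay + jitter + pd.Timedelta(days=10),
                                evidence="adult-killed")]
        elif status == "chick-lost":
            visits = [NestVisit(lay + jitter, adult=True, egg=True),
                      NestVisit(hatch + jitter, chick=True),
                      NestVisit(fledge + jitter)]
        else:  # successful
            visits = [NestVisit(lay + jitter, adult=True, egg=True),
                      NestVisit(hatch + jitter, chick=True),
                      NestVisit(fledge + jitter, chick=True, fledged=True)]
        records.append(NestRecord(nest_id=nest, season=config.season, visits=visits))
    return records, truth


# ---------------------------------------------------------------------------
# Two-group samples

def gen_two_group_samples(
    config: TwoGroupSimConfig, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normal draws for a two-group comparison (e.g. isotope values)."""
    rng = _rng(seed)
    if config.n1 < 2 or config.n2 < 2:
        raise ValueError("each group needs n >= 2")
    a = config.mean1 + config.sd1 * rng.standard_normal(config.n1)
    b = config.mean2 + config.sd2 * rng.standard_normal(config.n2)
    return a, b
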
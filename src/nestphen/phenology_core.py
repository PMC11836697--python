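"""Per-female and per-season nesting metrics from raw clutch records.

A nesting-beach monitoring programme yields one record per observed clutch:
the identity of the female (when she was encountered), the calendar date, and
up to three curved-carapace-length readings. This module turns those records
into the quantities the downstream trend analysis consumes:

* per female x season — first nest day-of-year, observed and estimated clutch
  frequency, binary breeding experience, mean size;
* per season — population first / median / last nest date, season duration,
  clutch counts and the proportion of clutches assigned to known females.

Estimated clutch frequency (ECF) imputes clutches missed by the survey (or
laid at another beach) from internesting intervals: typical intervals are
10–15 days, so a gap above 20, 30 or 45 days is read as one, two or three
missed clutches respectively.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: female_id value marking a clutch that could not be assigned to a female.
UNKNOWN = ""

EVENT_COLUMNS = ["female_id", "date", "ccl_1", "ccl_2", "ccl_3"]
SEASON_COLUMNS = [
    "female_id",
    "year",
    "first_nest_doy",
    "observed_cf",
    "estimated_cf",
    "experience",
    "mean_size_cm",
]


@dataclass(frozen=True)
class NestingEvent:
    """One observed clutch.

    ``female_id`` is an opaque tag string; :data:`UNKNOWN` (the empty string)
    marks clutches whose female was never encountered. ``size_measurements``
    holds 0–3 minimum curved carapace length readings in cm.
    """

    female_id: str
    date: dt.date
    size_measurements: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.date, dt.date) or isinstance(self.date, dt.datetime):
            raise TypeError("date must be a datetime.date")
        if len(self.size_measurements) > 3:
            raise ValueError("at most three size measurements per event")
        if any(not np.isfinite(s) or s <= 0 for s in self.size_measurements):
            raise ValueError("size measurements must be finite and positive")

    @property
    def year(self) -> int:
        return self.date.year

    @property
    def doy(self) -> int:
        return to_day_of_year(self.date)


@dataclass(frozen=True)
class FemaleSeason:
    """Metrics for one female in one nesting season."""

    female_id: str
    year: int
    first_nest_doy: int
    observed_cf: int
    estimated_cf: int
    experience: int  # 0 = new recruit, 1 = returning female
    mean_size_cm: float  # NaN when no readings were taken that season

    def __post_init__(self) -> None:
        if not 1 <= self.first_nest_doy <= 366:
            raise ValueError("first_nest_doy outside [1, 366]")
        if self.observed_cf < 1:
            raise ValueError("observed_cf must be >= 1")
        if self.estimated_cf < self.observed_cf:
            raise ValueError("estimated_cf must be >= observed_cf")
        if self.experience not in (0, 1):
            raise ValueError("experience must be 0 or 1")


@dataclass(frozen=True)
class SeasonSummary:
    """Population-level phenology metrics for one season."""

    year: int
    first_nest_doy: int
    median_nest_doy: float
    last_nest_doy: int
    duration_days: int
    n_clutches: int
    n_females_identified: int
    prop_clutches_assigned: float

    def __post_init__(self) -> None:
        if not self.first_nest_doy <= self.median_nest_doy <= self.last_nest_doy:
            raise ValueError("require first <= median <= last nest date")
        if self.duration_days < 0:
            raise ValueError("negative season duration")


@dataclass(frozen=True)
class StudyFilterConfig:
    """Which years feed which analysis, and the ECF imputation thresholds.

    Years with incomplete early-season survey coverage are dropped from the
    phenology metrics but still count towards a female's breeding experience.
    Early years in which recruits cannot be told from unmarked returners are
    additionally dropped from the individual-level dataset. Defaults mirror a
    1992–2022 monitoring programme: 1992, 2000, 2020 and 2021 excluded from
    all phenology, plus 1993–1994 from the individual-level analysis.
    """

    years_excluded_from_phenology: frozenset[int] = frozenset({1992, 2000, 2020, 2021})
    years_excluded_from_individual_analysis: frozenset[int] = frozenset({1993, 1994})
    years_counted_for_experience: frozenset[int] | None = None  # None = every year
    imputation_thresholds: tuple[int, int, int] = (20, 30, 45)

    def __post_init__(self) -> None:
        t = self.imputation_thresholds
        if not (len(t) == 3 and t[0] < t[1] < t[2]):
            raise ValueError("imputation thresholds must be three ascending gaps")

    @property
    def individual_excluded(self) -> frozenset[int]:
        """Years excluded from the individual-level dataset (union of both sets)."""
        return self.years_excluded_from_phenology | self.years_excluded_from_individual_analysis


def to_day_of_year(date: dt.date) -> int:
    """Day of year with 1 January = day 1, leap years counted (29 Feb = 60)."""
    if not isinstance(date, dt.date) or isinstance(date, dt.datetime):
        raise TypeError(f"expected datetime.date, got {type(date).__name__}")
    return date.timetuple().tm_yday


def estimate_clutch_frequency(
    sorted_clutch_doys: Sequence[int],
    thresholds: tuple[int, int, int] = (20, 30, 45),
) -> tuple[int, int]:
    """Observed and estimated clutch frequency for one female-season.

    The observed frequency is the number of recorded clutches. The estimated
    frequency adds, for each internesting gap ``g`` between consecutive
    recorded clutches, 1 missed clutch when ``t1 < g <= t2``, 2 when
    ``t2 < g <= t3`` and 3 when ``g > t3`` (defaults 20/30/45 days).

    Returns
    -------
    (observed_cf, estimated_cf)
    """
    doys = list(sorted_clutch_doys)
    if not doys:
        raise ValueError("need at least one clutch day")
    if any(b <= a for a, b in zip(doys, doys[1:])):
        raise ValueError("clutch days must be strictly increasing")
    t1, t2, t3 = thresholds
    missed = 0
    for a, b in zip(doys, doys[1:]):
        gap = b - a
        if gap > t3:
            missed += 3
        elif gap > t2:
            missed += 2
        elif gap > t1:
            missed += 1
    observed = len(doys)
    return observed, observed + missed


def code_breeding_experience(
    female_id: str,
    year: int,
    nesting_history: set[tuple[str, int]],
) -> int:
    """0 for a first-ever recorded season, 1 for a returning female.

    ``nesting_history`` must contain every (female, year) pair ever recorded —
    including years excluded from the phenology analyses, which still count
    as completed seasons.
    """
    if (female_id, year) not in nesting_history:
        raise ValueError(f"female {female_id!r} has no recorded season in {year}")
    return int(any(f == female_id and y < year for f, y in nesting_history))


def _events_frame(events: Iterable[NestingEvent] | pd.DataFrame) -> pd.DataFrame:
    """Normalize events to a DataFrame with female_id/year/doy/sizes columns."""
    if isinstance(events, pd.DataFrame):
        df = events.copy()
        if {"female_id", "year", "doy", "sizes"} <= set(df.columns):
            return df[["female_id", "year", "doy", "sizes"]]
        if "date" not in df.columns:
            raise ValueError("events frame needs a 'date' column")
        dates = pd.to_datetime(df["date"])
        df["year"] = dates.dt.year.to_numpy()
        df["doy"] = dates.dt.dayofyear.to_numpy()
        df["female_id"] = df["female_id"].fillna(UNKNOWN).astype(str)
        size_cols = [c for c in ("ccl_1", "ccl_2", "ccl_3") if c in df.columns]
        df["sizes"] = [
            tuple(v for v in row if pd.notna(v)) for row in df[size_cols].to_numpy()
        ] if size_cols else [()] * len(df)
        return df[["female_id", "year", "doy", "sizes"]]
    rows = [(e.female_id, e.year, e.doy, e.size_measurements) for e in events]
    return pd.DataFrame(rows, columns=["female_id", "year", "doy", "sizes"])


def nesting_history(
    events: Iterable[NestingEvent] | pd.DataFrame,
    filters: StudyFilterConfig | None = None,
) -> set[tuple[str, int]]:
    """All (female, year) pairs ever recorded, for breeding-experience coding."""
    filters = filters or StudyFilterConfig()
    df = _events_frame(events)
    df = df[df["female_id"] != UNKNOWN]
    if filters.years_counted_for_experience is not None:
        df = df[df["year"].isin(filters.years_counted_for_experience)]
    return set(zip(df["female_id"], df["year"].astype(int)))


def build_female_seasons(
    events: Iterable[NestingEvent] | pd.DataFrame,
    filters: StudyFilterConfig | None = None,
) -> list[FemaleSeason]:
    """One :class:`FemaleSeason` per identified female per retained year.

    Events in years excluded from the individual-level analysis still enter
    the breeding-experience history, but yield no output record; events with
    an unknown female feed only the population summaries and are ignored here.
    """
    filters = filters or StudyFilterConfig()
    df = _events_frame(events)
    df = df[df["female_id"] != UNKNOWN]
    if df.empty:
        return []
    history = nesting_history(df, filters)
    excluded = filters.individual_excluded
    out: list[FemaleSeason] = []
    for (fid, year), grp in df.groupby(["female_id", "year"], sort=True):
        year = int(year)
        if year in excluded:
            continue
        doys = sorted(set(grp["doy"].astype(int)))
        ocf, ecf = estimate_clutch_frequency(doys, filters.imputation_thresholds)
        sizes = [s for tup in grp["sizes"] for s in tup]
        out.append(
            FemaleSeason(
                female_id=str(fid),
                year=year,
                first_nest_doy=doys[0],
                observed_cf=ocf,
                estimated_cf=ecf,
                experience=code_breeding_experience(str(fid), year, history),
                mean_size_cm=float(np.mean(sizes)) if sizes else float("nan"),
            )
        )
    return out


def summarize_seasons(
    events: Iterable[NestingEvent] | pd.DataFrame,
    filters: StudyFilterConfig | None = None,
) -> list[SeasonSummary]:
    """Population phenology per retained year, over ALL clutches.

    Unassigned clutches count towards the first/median/last dates and totals;
    the median is taken across every clutch laid that year. Years without any
    event are simply absent from the output.
    """
    filters = filters or StudyFilterConfig()
    df = _events_frame(events)
    out: list[SeasonSummary] = []
    for year, grp in df.groupby("year", sort=True):
        year = int(year)
        if year in filters.years_excluded_from_phenology:
            continue
        doys = grp["doy"].astype(int)
        assigned = grp[grp["female_id"] != UNKNOWN]
        first, last = int(doys.min()), int(doys.max())
        out.append(
            SeasonSummary(
                year=year,
                first_nest_doy=first,
                median_nest_doy=float(doys.median()),
                last_nest_doy=last,
                duration_days=last - first,
                n_clutches=len(grp),
                n_females_identified=assigned["female_id"].nunique(),
                prop_clutches_assigned=len(assigned) / len(grp),
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV interfaces


def events_to_frame(events: Iterable[NestingEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        sizes = list(e.size_measurements) + [None] * (3 - len(e.size_measurements))
        rows.append([e.female_id, e.date.isoformat(), *sizes])
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[NestingEvent]:
    events = []
    for row in df.itertuples(index=False):
        fid = "" if pd.isna(row.female_id) else str(row.female_id)
        sizes = tuple(
            float(v)
            for v in (row.ccl_1, row.ccl_2, row.ccl_3)
            if v is not None and not pd.isna(v)
        )
        events.append(NestingEvent(fid, dt.date.fromisoformat(str(row.date)), sizes))
    return events


def read_events_csv(path) -> list[NestingEvent]:
    """Read a nesting-events CSV (``female_id,date,ccl_1,ccl_2,ccl_3``)."""
    df = pd.read_csv(path, dtype={"female_id": str}, keep_default_na=True)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns: {sorted(missing)}")
    df["female_id"] = df["female_id"].fillna(UNKNOWN)
    return frame_to_events(df)


def write_events_csv(events: Iterable[NestingEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def seasons_to_frame(seasons: Iterable[FemaleSeason]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.female_id, s.year, s.first_nest_doy, s.observed_cf, s.estimated_cf, s.experience, s.mean_size_cm)
            for s in seasons
        ],
        columns=SEASON_COLUMNS,
    )


def frame_to_seasons(df: pd.DataFrame) -> list[FemaleSeason]:
    return [
        FemaleSeason(
            str(r.female_id),
            int(r.year),
            int(r.first_nest_doy),
            int(r.observed_cf),
            int(r.estimated_cf),
            int(r.experience),
            float(r.mean_size_cm) if not pd.isna(r.mean_size_cm) else float("nan"),
        )
        for r in df.itertuples(index=False)
    ]


def read_seasons_csv(path) -> list[FemaleSeason]:
    df = pd.read_csv(path, dtype={"female_id": str})
    missing = set(SEASON_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"seasons CSV missing columns: {sorted(missing)}")
    return frame_to_seasons(df)


def write_seasons_csv(seasons: Iterable[FemaleSeason], path) -> None:
    seasons_to_frame(seasons).to_csv(path, index=False)


def summaries_to_frame(summaries: Iterable[SeasonSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.year,
                s.first_nest_doy,
                s.median_nest_doy,
                s.last_nest_doy,
                s.duration_days,
                s.n_clutches,
                s.n_females_identified,
                s.prop_clutches_assigned,
            )
            for s in summaries
        ],
        columns=[
            "year",
            "first_nest_doy",
            "median_nest_doy",
            "last_nest_doy",
            "duration_days",
            "n_clutches",
            "n_females_identified",
            "prop_clutches_assigned",
        ],
    )


def write_summaries_csv(summaries: Iterable[SeasonSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)
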
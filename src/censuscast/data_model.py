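"""Core domain types and the census accounting ledger.

A hospital unit's end-of-day census evolves by the identity

    C(t + k) = C(t) + sum_{i=1..k} A(t + i) - sum_{i=1..k} D(t + i)

where ``A`` counts admissions during a calendar day and ``D`` counts
(healthy) discharges.  This module defines the patient-level record, the
census state at a day, and the two operations every other module leans on:
deriving a census state from patient records and evaluating the identity.

Day convention
--------------
Days are 0-based integers on a shared calendar.  A patient admitted on day
``a`` with length of stay ``L`` appears in the end-of-day (11:59pm) census on
days ``a, a+1, ..., a+L-1``; day-of-stay is ``s = day - a`` (so ``s = 0`` on
the admission day).  The departure is recorded in ``D(a+L)``, the first day
the patient is absent from the snapshot.  Under this convention the
departure indicator ``Y^(k,s) = 1{LOS <= k+s}`` is exactly the event
"absent from the census at end of day t+k" for a patient with ``s`` days
spent at day ``t``.

Stays shorter than one full day (``los = 0``) are rejected, mirroring the
">24 hours" inclusion rule for unit admissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

__all__ = [
    "PatientRecord",
    "CensusState",
    "DailyFlow",
    "SCORE_AVAILABILITY",
    "build_census_state",
    "census_identity",
    "daily_flows",
    "censor_record",
    "record_range",
]

#: day-of-stay at which each time-varying severity score becomes available.
#: A score is defined only for patients whose stay reaches that day-of-stay.
SCORE_AVAILABILITY: Mapping[str, int] = {
    "snapdol1": 1,
    "main1": 1,
    "snapdol3": 3,
    "main7": 7,
}

BASELINE_COVARIATES = ("bweight", "gestage")


@dataclass(frozen=True)
class PatientRecord:
    """One admitted patient.

    Exactly one of ``los`` (known length of stay, days) and ``censored_at``
    (still present after that many days of stay; LOS > censored_at) is set.
    Time-varying severity scores are ``None`` whenever the (possibly
    censored) stay never reaches the score's availability day-of-stay.
    """

    patient_id: str
    admit_day: int
    los: Optional[int] = None
    censored_at: Optional[int] = None
    bweight: Optional[float] = None
    gestage: Optional[float] = None
    snapdol1: Optional[float] = None
    main1: Optional[float] = None
    snapdol3: Optional[float] = None
    main7: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.los is None) == (self.censored_at is None):
            raise ValueError(
                f"patient {self.patient_id}: exactly one of los/censored_at "
                "must be set"
            )
        if self.los is not None and self.los < 1:
            raise ValueError(
                f"patient {self.patient_id}: los must be >= 1 day "
                f"(got {self.los}); same-day stays are excluded"
            )
        if self.censored_at is not None and self.censored_at < 0:
            raise ValueError(
                f"patient {self.patient_id}: censored_at must be >= 0"
            )
        for name, avail_day in SCORE_AVAILABILITY.items():
            if getattr(self, name) is not None and self.max_stay_day < avail_day:
                raise ValueError(
                    f"patient {self.patient_id}: {name} present but stay "
                    f"never reaches day-of-stay {avail_day}"
                )

    @property
    def is_censored(self) -> bool:
        return self.censored_at is not None

    @property
    def max_stay_day(self) -> int:
        """Largest day-of-stay s the patient is known to reach."""
        if self.los is not None:
            return self.los - 1
        return self.censored_at  # type: ignore[return-value]

    def present_on(self, day: int) -> bool:
        """In the end-of-day census on ``day``?  Censored patients count as
        present through their censoring day."""
        return self.admit_day <= day <= self.admit_day + self.max_stay_day

    def covariate(self, name: str) -> Optional[float]:
        return getattr(self, name)


@dataclass(frozen=True)
class CensusState:
    """The unit at the end of one calendar day."""

    day: int
    present: tuple  # of (PatientRecord, s) pairs, s = days already spent
    census_count: int = field(init=False)
    occupancy_by_stay: Mapping[int, int] = field(init=False)

    def __post_init__(self) -> None:
        occ: dict[int, int] = {}
        for rec, s in self.present:
            if s < 0:
                raise ValueError(f"negative day-of-stay {s} for {rec.patient_id}")
            occ[s] = occ.get(s, 0) + 1
        object.__setattr__(self, "census_count", len(self.present))
        object.__setattr__(self, "occupancy_by_stay", occ)


@dataclass(frozen=True)
class DailyFlow:
    """Arrivals A(t) and departures D(t) on one calendar day."""

    day: int
    arrivals: int
    departures: int

    def __post_init__(self) -> None:
        if self.arrivals < 0 or self.departures < 0:
            raise ValueError("arrivals and departures must be nonnegative")


def record_range(records: Sequence[PatientRecord]) -> tuple[int, int]:
    """Calendar range covered by the records: first admission day through the
    last day any patient is known to be present."""
    if not records:
        raise ValueError("no records")
    lo = min(r.admit_day for r in records)
    hi = max(r.admit_day + r.max_stay_day for r in records)
    return lo, hi


def build_census_state(
    records: Sequence[PatientRecord],
    day: int,
    *,
    calendar_range: Optional[tuple[int, int]] = None,
) -> CensusState:
    """Derive the end-of-day census state at ``day`` from patient records.

    A record is present iff ``admit_day <= day`` and the stay (known LOS, or
    censoring lower bound) has not ended: ``day <= admit_day + max_stay_day``.

    Raises
    ------
    ValueError
        If ``day`` lies outside the covered calendar range (or the supplied
        ``calendar_range``).
    """
    lo, hi = calendar_range if calendar_range is not None else record_range(records)
    if not lo <= day <= hi:
        raise ValueError(f"day {day} outside covered range [{lo}, {hi}]")
    present = tuple(
        (r, day - r.admit_day) for r in records if r.present_on(day)
    )
    return CensusState(day=day, present=present)


def census_identity(
    c_t: int, arrivals: Sequence[int], cum_departures: int
) -> int:
    """Census accounting identity: C(t+k) = C(t) + sum(A) - cumulative D.

    Raises
    ------
    ValueError
        If more patients depart than were ever present.
    """
    if c_t < 0 or cum_departures < 0 or any(a < 0 for a in arrivals):
        raise ValueError("census, arrivals and departures must be nonnegative")
    total_in = c_t + sum(arrivals)
    if cum_departures > total_in:
        raise ValueError(
            f"{cum_departures} departures exceed the {total_in} patients "
            "ever present"
        )
    return total_in - cum_departures


def daily_flows(
    records: Sequence[PatientRecord], days: Sequence[int]
) -> list[DailyFlow]:
    """True A(t), D(t) per day.  D(t) counts patients whose first absent day
    is ``t`` (admit_day + los == t); censored stays never generate a
    departure."""
    arr: dict[int, int] = {}
    dep: dict[int, int] = {}
    for r in records:
        arr[r.admit_day] = arr.get(r.admit_day, 0) + 1
        if r.los is not None:
            d = r.admit_day + r.los
            dep[d] = dep.get(d, 0) + 1
    return [
        DailyFlow(day=t, arrivals=arr.get(t, 0), departures=dep.get(t, 0))
        for t in days
    ]


def censor_record(rec: PatientRecord, cutoff_day: int) -> Optional[PatientRecord]:
    """The record as knowable at end of ``cutoff_day`` (no information leak).

    Returns ``None`` if the patient has not been admitted by the cutoff.
    A patient still present at the cutoff becomes censored at
    ``c = cutoff_day - admit_day`` (LOS > c), with any severity score whose
    availability day exceeds ``c`` hidden.
    """
    if rec.admit_day > cutoff_day:
        return None
    last_present = rec.admit_day + rec.max_stay_day
    if rec.los is not None and last_present < cutoff_day:
        return rec  # departure already observed; fully known
    c = cutoff_day - rec.admit_day
    if rec.censored_at is not None and rec.censored_at <= c:
        return rec  # already censored earlier than the cutoff implies
    hidden = {
        name: None
        for name, avail in SCORE_AVAILABILITY.items()
        if avail > c
    }
    return replace(rec, los=None, censored_at=c, **hidden)
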
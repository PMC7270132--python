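"""Therapies, dose events and the named administration protocols.

Seven therapies are supported:

======  ==========================================================
CX      androgen deprivation ("castration"): a forcing interval
        during which androgen decays exponentially
V       dendritic-cell vaccine, sets the vaccine drug level
AI      anti-IL-2 antibody, sets ``anti_I``
AR      anti-Treg (anti-CD25) antibody, sets ``anti_R``
NK      adoptive NK-cell transfer: raises the NK initial condition
        by ``nk_injection_multiplier`` x dose (time-0 only)
ICB     checkpoint blockade cocktail, sets ``I_CB``; 3x/week
AM      anti-MDSC drug (short half-life), sets ``anti_M``; daily
======  ==========================================================

Administration *resets* the drug variable to the dose amount (it does not
accumulate on top of the residual level); between doses each drug decays
with its own first-order rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .model import DRUG_STATE_OF_THERAPY, SystemState
from .parameters import ParameterSet

__all__ = ["THERAPIES", "DoseEvent", "TreatmentSchedule", "apply_dose",
           "standard_protocol", "adt_then_immunotherapy_protocol",
           "calibration_protocol", "parse_combo"]

THERAPIES = ("CX", "V", "AI", "AR", "NK", "ICB", "AM")

WEEK = 7.0
#: Dose days within one week for the thrice-weekly checkpoint blockade.
ICB_WEEKLY_PATTERN = (0.0, 2.0, 4.0)


def _check_therapy(name: str) -> str:
    if name not in THERAPIES:
        raise ValueError(f"unknown therapy {name!r}; expected one of "
                         f"{', '.join(THERAPIES)}")
    return name


def parse_combo(spec: str | Iterable[str]) -> tuple[str, ...]:
    """Normalise a combination like ``"CX+V+ICB"`` (or any iterable of
    therapy names) into a sorted, duplicate-free tuple."""
    if isinstance(spec, str):
        parts = [p.strip().upper() for p in spec.split("+") if p.strip()]
    else:
        parts = [str(p).upper() for p in spec]
    combo = sorted({_check_therapy(p) for p in parts},
                   key=THERAPIES.index)
    return tuple(combo)


@dataclass(frozen=True)
class DoseEvent:
    therapy: str
    time: float
    amount: float = 1.0

    def __post_init__(self) -> None:
        _check_therapy(self.therapy)
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.therapy == "NK" and self.time != 0:
            raise ValueError("NK transfer is an initial-condition mechanism; "
                             "events are only supported at time 0")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered dose events plus the androgen-deprivation forcing interval."""

    events: tuple[DoseEvent, ...] = ()
    cx_interval: Optional[tuple[float, float]] = None
    horizon: float = 49.0

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if any(e.time > self.horizon for e in events):
            raise ValueError("dose events must not occur after the horizon")
        if self.cx_interval is not None:
            start, end = self.cx_interval
            if not 0 <= start < end:
                raise ValueError(f"invalid cx_interval {self.cx_interval}")

    def cx_active(self, t: float) -> bool:
        if self.cx_interval is None:
            return False
        start, end = self.cx_interval
        return start <= t < end

    def scale_therapy(self, therapy: str, factor: float) -> "TreatmentSchedule":
        """Schedule with every dose of one therapy scaled by ``factor``."""
        _check_therapy(therapy)
        events = tuple(
            replace(e, amount=e.amount * factor) if e.therapy == therapy else e
            for e in self.events)
        return replace(self, events=events)

    @property
    def therapies(self) -> tuple[str, ...]:
        names = {e.therapy for e in self.events}
        if self.cx_interval is not None:
            names.add("CX")
        return tuple(sorted(names, key=THERAPIES.index))


def apply_dose(state: SystemState, event: DoseEvent,
               params: ParameterSet) -> SystemState:
    """State immediately after one dose event.

    Drug doses reset the matching drug variable to the dose amount; an NK
    event raises N to ``1 + multiplier * amount`` (pre-existing pool plus
    the transferred cells); CX leaves the state untouched (it acts through
    the schedule's forcing interval).
    """
    if event.therapy == "CX":
        return state
    if event.therapy == "NK":
        return state.replace(
            N=state.N + params.nk_injection_multiplier * event.amount)
    return state.replace(**{DRUG_STATE_OF_THERAPY[event.therapy]: event.amount})


def _icb_events(start: float, weeks: int, amount: float = 1.0):
    return [DoseEvent("ICB", start + WEEK * k + offset, amount)
            for k in range(weeks) for offset in ICB_WEEKLY_PATTERN]


def _daily_events(therapy: str, start: float, days: int, amount: float = 1.0):
    return [DoseEvent(therapy, start + d, amount) for d in range(days)]


def standard_protocol(combo: str | Iterable[str],
                      amount: float = 1.0) -> TreatmentSchedule:
    """The uniform 4-week screening protocol: every selected therapy starts
    at day 0 and runs through day 28.

    CX is active over the whole window; V/AI/AR/NK are a single bolus at
    day 0 (their week-scale half-lives sustain exposure); ICB is dosed
    three times per week (days {0, 2, 4} of each week) and AM daily.
    """
    combo = parse_combo(combo)
    if not combo:
        raise ValueError("combo must contain at least one therapy")
    events: list[DoseEvent] = []
    cx_interval = None
    for therapy in combo:
        if therapy == "CX":
            cx_interval = (0.0, 28.0)
        elif therapy == "ICB":
            events.extend(_icb_events(0.0, 4, amount))
        elif therapy == "AM":
            events.extend(_daily_events("AM", 0.0, 28, amount))
        else:  # V, AI, AR, NK: single dose at t = 0
            events.append(DoseEvent(therapy, 0.0, amount))
    return TreatmentSchedule(events=tuple(events), cx_interval=cx_interval,
                             horizon=28.0)


def adt_then_immunotherapy_protocol(
        combo: str | Iterable[str] = (),
        amount: float = 1.0) -> TreatmentSchedule:
    """Androgen deprivation from day 0, immunotherapy from day 21.

    Mirrors the pre-clinical design in which castration-resistant disease is
    allowed to develop for three weeks before checkpoint blockade (3x/week)
    and/or the anti-MDSC drug (daily) are given for four weeks, with endpoint
    at week 7 (day 49). Only ICB and AM are supported as add-ons.
    """
    combo = parse_combo(combo) if combo else ()
    bad = [t for t in combo if t not in ("ICB", "AM")]
    if bad:
        raise ValueError("only ICB and AM can follow androgen deprivation in "
                         f"this protocol; got {', '.join(bad)}")
    events: list[DoseEvent] = []
    if "ICB" in combo:
        events.extend(_icb_events(21.0, 4, amount))
    if "AM" in combo:
        events.extend(_daily_events("AM", 21.0, 28, amount))
    return TreatmentSchedule(events=tuple(events), cx_interval=(0.0, 49.0),
                             horizon=49.0)


def calibration_protocol(combo: str | Iterable[str] = (),
                         horizon: float = 35.0) -> TreatmentSchedule:
    """Protocol used for the fold-change calibration scenarios: every therapy
    starts at day 0 and the simulation runs to ``horizon`` (default 5 weeks,
    the span of the observed time series). Dosing patterns per therapy match
    :func:`standard_protocol`, with CX active over the whole horizon."""
    combo = parse_combo(combo) if combo else ()
    events: list[DoseEvent] = []
    cx_interval = None
    weeks = int(horizon // WEEK)
    for therapy in combo:
        if therapy == "CX":
            cx_interval = (0.0, horizon)
        elif therapy == "ICB":
            events.extend(e for e in _icb_events(0.0, weeks)
                          if e.time <= horizon)
        elif therapy == "AM":
            events.extend(_daily_events("AM", 0.0, int(horizon)))
        else:
            events.append(DoseEvent(therapy, 0.0))
    return TreatmentSchedule(events=tuple(events), cx_interval=cx_interval,
                             horizon=horizon)
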
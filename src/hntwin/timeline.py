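"""Treatment timelines: cycle segmentation and the single-cycle reduction.

A raw patient history is a day-stamped event log of interventions (actions)
and disease-status assessments.  Treatment unfolds in cycles of
``[action(s), status...]`` closed by a relapse/recurrence; for modeling, a
multi-cycle history is reduced to the first-cycle actions plus a year-3
outcome — intermediate interventions are treated as latent.

First-cycle actions are decoded into three variables: definitive surgery
(no/yes), induction chemotherapy (no/yes), and radiotherapy
(no/yes/yes-with-concurrent-chemotherapy).  Chemotherapy delivered within the
concurrency window of a radiation course counts as concurrent; chemotherapy
further ahead of radiation counts as induction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

AVG_DAYS_PER_MONTH = 30.44

RELAPSE = "Relapse/Recurrence"
CONCURRENT_LABEL = "radiotherapy (w/ concurrent chemotherapy)"

#: default window (days) within which chemotherapy + radiation are considered
#: one concurrent course; histories show concurrent pairs ~5 days apart and
#: distinct-course gaps of months, so 45 days separates the regimes with
#: margin.  Configurable everywhere it is used.
DEFAULT_MERGE_WINDOW = 45

DEFAULT_HORIZON = 1095          # three years, in days
STATUS_GRACE_DAYS = 90          # tolerance when locating the year-3 status

_SURGERY = ("surgery",)
_CHEMO = ("chemotherapy", "chemo")
_RADIATION = ("radiation",)


@dataclass(frozen=True)
class Event:
    day: int
    category: str  # 'Action' | 'Status' | 'TreatmentStart'
    procedure: str

    def __post_init__(self):
        if self.day < 0:
            raise ValueError(f"event day must be >= 0, got {self.day}")


@dataclass
class Cycle:
    actions: list[Event] = field(default_factory=list)
    statuses: list[Event] = field(default_factory=list)

    @property
    def closed_by_relapse(self) -> bool:
        return any(s.procedure == RELAPSE for s in self.statuses)


@dataclass
class SimplifiedRecord:
    definitive: str = "no"
    induction: str = "no"
    radio_chemo: str = "no"
    status_yr3: str | None = None
    relapse_yr3: bool | None = None

    def as_pattern(self) -> tuple[str, str, str]:
        return (self.definitive, self.induction, self.radio_chemo)


def _kind(procedure: str) -> str:
    p = procedure.lower()
    if any(k in p for k in _SURGERY):
        return "surgery"
    if any(k in p for k in _RADIATION):
        return "radiation"
    if any(k in p for k in _CHEMO):
        return "chemotherapy"
    return "other"


def read_event_log(path) -> list[Event]:
    """Read an event-log CSV with columns day, category, procedure."""
    df = pd.read_csv(path)
    required = {"day", "category", "procedure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"event log missing column(s): {', '.join(sorted(missing))}")
    return [Event(int(r.day), str(r.category), str(r.procedure))
            for r in df.itertuples()]


def segment_cycles(events: Iterable[Event],
                   merge_window_days: int = DEFAULT_MERGE_WINDOW) -> list[Cycle]:
    """Partition a log into treatment cycles closed by relapse events.

    A cycle collects all actions and statuses (in day order) up to and
    including the relapse/recurrence that closes it; events after the relapse
    open the next cycle.  Within a cycle, a chemotherapy and a radiation
    action no more than ``merge_window_days`` apart are merged into a single
    concurrent-chemoradiotherapy action.  Status events that precede any
    action are attached to the first cycle with a warning.
    """
    events = sorted(events, key=lambda e: e.day)
    cycles: list[Cycle] = []
    current = Cycle()
    seen_action = False
    for ev in events:
        if ev.category == "TreatmentStart":
            continue
        if ev.category == "Action":
            if current.closed_by_relapse:
                cycles.append(current)
                current = Cycle()
            current.actions.append(ev)
            seen_action = True
        elif ev.category == "Status":
            if not seen_action:
                log.warning("status %r at day %d precedes any action; "
                            "attached to first cycle", ev.procedure, ev.day)
            current.statuses.append(ev)
        else:
            raise ValueError(f"unknown event category {ev.category!r}")
    if current.actions or current.statuses:
        cycles.append(current)
    for cyc in cycles:
        cyc.actions = _merge_concurrent(cyc.actions, merge_window_days)
    return cycles


def _merge_concurrent(actions: list[Event], window: int) -> list[Event]:
    """Merge chemo + radiation pairs within ``window`` days into one action."""
    merged: list[Event] = []
    used = [False] * len(actions)
    for i, a in enumerate(actions):
        if used[i]:
            continue
        if _kind(a.procedure) == "chemotherapy":
            partner = next(
                (j for j, b in enumerate(actions)
                 if not used[j] and j != i and _kind(b.procedure) == "radiation"
                 and abs(b.day - a.day) <= window),
                None,
            )
            if partner is not None:
                used[i] = used[partner] = True
                day = min(a.day, actions[partner].day)
                merged.append(Event(day, "Action", CONCURRENT_LABEL))
                continue
        used[i] = True
        merged.append(a)
    merged.sort(key=lambda e: e.day)
    return merged


def simplify_to_single_cycle(cycles: list[Cycle],
                             horizon_days: int = DEFAULT_HORIZON,
                             merge_window_days: int = DEFAULT_MERGE_WINDOW,
                             ) -> SimplifiedRecord:
    """Reduce a multi-cycle history to first-cycle actions + year-3 outcome.

    ``relapse_yr3`` is True iff any relapse event occurs on or before the
    horizon; False when follow-up reaches the horizon (within the grace
    window) without relapse; missing when follow-up is too short to tell.
    ``status_yr3`` is the status nearest the horizon within +-90 days, or the
    latest pre-horizon status as a fallback.
    """
    if not cycles:
        raise ValueError("cannot simplify an empty cycle list")
    rec = SimplifiedRecord()
    first = cycles[0]

    radiation_days = [a.day for a in first.actions
                      if _kind(a.procedure) == "radiation"
                      or a.procedure == CONCURRENT_LABEL]
    for a in first.actions:
        kind = _kind(a.procedure)
        if kind == "surgery":
            rec.definitive = "yes"
        elif a.procedure == CONCURRENT_LABEL:
            rec.radio_chemo = "yes-with-concurrent-chemotherapy"
        elif kind == "radiation":
            if rec.radio_chemo == "no":
                rec.radio_chemo = "yes"
        elif kind == "chemotherapy":
            # un-merged chemo preceding radiation by more than the window
            if any(rt - a.day > merge_window_days for rt in radiation_days):
                rec.induction = "yes"
        else:
            log.warning("unrecognized action %r ignored in simplification",
                        a.procedure)

    statuses = [s for cyc in cycles for s in cyc.statuses]
    relapse_days = [s.day for s in statuses if s.procedure == RELAPSE]
    if any(d <= horizon_days for d in relapse_days):
        rec.relapse_yr3 = True
    elif statuses and max(s.day for s in statuses) >= horizon_days - STATUS_GRACE_DAYS:
        rec.relapse_yr3 = False
    else:
        rec.relapse_yr3 = None

    near = [s for s in statuses if abs(s.day - horizon_days) <= STATUS_GRACE_DAYS]
    if near:
        rec.status_yr3 = min(near, key=lambda s: abs(s.day - horizon_days)).procedure
    else:
        before = [s for s in statuses if s.day <= horizon_days]
        rec.status_yr3 = max(before, key=lambda s: s.day).procedure if before else None
    return rec


def elapsed_months(day_a: int, day_b: int) -> int:
    """Whole months between two day stamps (average month = 30.44 days)."""
    if day_b < day_a:
        raise ValueError(f"day_b ({day_b}) must be >= day_a ({day_a})")
    return int(math.floor((day_b - day_a) / AVG_DAYS_PER_MONTH + 0.5))


# ---------------------------------------------------------------------------
# Pattern mining
# ---------------------------------------------------------------------------

def _pattern_string(pattern: tuple[str, str, str]) -> str:
    ds, ic, rc = pattern
    parts = [
        "definitive surgery" if ds == "yes" else "n/a",
        "induction therapy" if ic == "yes" else "n/a",
        {"no": "n/a", "yes": "radiotherapy",
         "yes-with-concurrent-chemotherapy": CONCURRENT_LABEL}[rc],
    ]
    return " -> ".join(parts)


def mine_sequence_patterns(records: list[SimplifiedRecord]) -> pd.DataFrame:
    """Count (definitive, induction, radio/chemo) triples, sorted descending.

    Returns a frame with columns ``treatment_sequence`` (rendered
    ``x -> y -> z`` strings) and ``count``.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for rec in records:
        key = rec.as_pattern()
        counts[key] = counts.get(key, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], _pattern_string(kv[0])))
    return pd.DataFrame(
        {"treatment_sequence": [_pattern_string(k) for k, _ in rows],
         "count": [c for _, c in rows]}
    )
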
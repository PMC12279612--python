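"""Prescription state timelines, transitions, and the 8x8 transition matrix.

A patient's exposure to each of three drug groups -- opioids (O),
benzodiazepines (B), and non-benzodiazepine sedative-hypnotics (S) -- is
reconstructed from prescription fill events (fill date + days supply).  At
any day the patient occupies one of ``2**3 = 8`` prescription states: the
subset of groups with an active (non-lapsed) fill, encoded as a 3-bit mask.
State changes define transitions; pooled transition counts ``C[i, j]`` are
row-normalized into the transition-probability matrix ``pi[i, j]``.

All times are integer days and intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "O", "B", "S", "STATE_MASKS", "STATE_NAMES",
    "state_name", "state_index", "collapse_drug_count",
    "FillEvent", "StateTimeline", "TransitionRecord", "TransitionMatrix",
    "AttributionError",
    "fills_to_exposure", "build_state_timeline", "enumerate_transitions",
    "assign_responsible_physician", "count_transition_matrix",
    "obs_duration_records", "opioid_focus_records",
    "analyze_patient", "analyze_cohort", "transitions_to_frame",
]

# Bit masks for the three drug groups.
O, B, S = 1, 2, 4
GROUPS = (O, B, S)
GROUP_LETTERS = {O: "O", B: "B", S: "S"}
LETTER_GROUPS = {"O": O, "B": B, "S": S}

#: Canonical state order: zero, O, B, S, OB, OS, BS, OBS.
STATE_MASKS = (0, O, B, S, O | B, O | S, B | S, O | B | S)
STATE_NAMES = ("zero", "O", "B", "S", "OB", "OS", "BS", "OBS")
_MASK_TO_INDEX = {m: i for i, m in enumerate(STATE_MASKS)}
OBS_MASK = O | B | S


class AttributionError(ValueError):
    """Raised when a transition cannot be attributed to a prescriber."""


def state_name(mask: int) -> str:
    """Human-readable name ("zero" ... "OBS") for a state bit mask."""
    return STATE_NAMES[_MASK_TO_INDEX[mask]]


def state_index(mask: int) -> int:
    """Position of a state mask in the canonical 8-state order."""
    return _MASK_TO_INDEX[mask]


def collapse_drug_count(mask: int) -> int:
    """Number of distinct drug groups in a state (0-3).

    Collapsing the 8 states by drug count yields the 4-category model:
    states {O, B, S} map to 1, {OB, OS, BS} to 2, and OBS to 3.
    """
    if mask not in _MASK_TO_INDEX:
        raise ValueError(f"invalid state mask: {mask!r}")
    return bin(mask).count("1")


@dataclass(frozen=True)
class FillEvent:
    """One prescription fill: who prescribed what group, when, for how long."""

    patient_id: str
    prescriber_id: str
    drug_group: int  # O, B or S bit
    fill_date: int
    days_supply: int

    def __post_init__(self) -> None:
        if self.drug_group not in GROUPS:
            raise ValueError(f"unknown drug group: {self.drug_group!r}")
        if self.days_supply < 1:
            raise ValueError("days_supply must be >= 1")
        if self.fill_date < 0:
            raise ValueError("fill_date must be >= 0")


@dataclass
class StateTimeline:
    """Maximal constant-state segments ``(mask, start, end)`` for one patient."""

    patient_id: str
    segments: list[tuple[int, int, int]] = field(default_factory=list)

    def state_at(self, day: int) -> int:
        for mask, start, end in self.segments:
            if start <= day < end:
                return mask
        raise ValueError(f"day {day} outside timeline")


@dataclass
class TransitionRecord:
    """One state change, with the physician held responsible for it."""

    patient_id: str
    t_index: int
    from_mask: int
    to_mask: int
    date: int
    responsible_physician_id: str
    ambiguous: bool = False

    @property
    def drug_count_from(self) -> int:
        return collapse_drug_count(self.from_mask)

    @property
    def drug_count_to(self) -> int:
        return collapse_drug_count(self.to_mask)


@dataclass
class TransitionMatrix:
    """8x8 transition counts and row-normalized probabilities.

    The diagonal is structurally zero: refills that re-enter the current
    state are not treated as transitions.  Rows with no observed
    transitions have undefined probabilities (NaN) and are flagged in
    ``defined_rows``.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    defined_rows: np.ndarray  # boolean, length 8

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kind, mat in (("count", self.counts), ("probability", self.probabilities)):
            df = pd.DataFrame(mat, index=STATE_NAMES, columns=STATE_NAMES)
            df.insert(0, "kind", kind)
            df.index.name = "from_state"
            rows.append(df.reset_index())
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Exposure interval algebra
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or abutting runs merge."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def fills_to_exposure(
    fills: Sequence[FillEvent], mode: str = "union"
) -> dict[int, list[tuple[int, int]]]:
    """Convert one patient's fills into per-group disjoint exposure intervals.

    ``mode="union"`` (default): each fill covers ``[fill_date,
    fill_date + days_supply)`` and overlapping same-group coverage is
    unioned -- early refills do not stockpile supply.  ``mode="extension"``:
    a fill placed while a previous one is still active starts its supply
    when the previous one ends, so supply accumulates.
    """
    if mode not in ("union", "extension"):
        raise ValueError(f"unknown exposure mode: {mode!r}")
    by_group: dict[int, list[FillEvent]] = {}
    for f in fills:
        if f.drug_group not in GROUPS:
            raise ValueError(f"unknown drug group: {f.drug_group!r}")
        by_group.setdefault(f.drug_group, []).append(f)

    exposure: dict[int, list[tuple[int, int]]] = {}
    for group, group_fills in by_group.items():
        group_fills = sorted(group_fills, key=lambda f: (f.fill_date, f.prescriber_id))
        if mode == "union":
            exposure[group] = _merge_intervals(
                [(f.fill_date, f.fill_date + f.days_supply) for f in group_fills]
            )
        else:  # extension: queue unused supply behind the active interval
            intervals: list[tuple[int, int]] = []
            for f in group_fills:
                if intervals and f.fill_date <= intervals[-1][1]:
                    intervals[-1] = (intervals[-1][0], intervals[-1][1] + f.days_supply)
                else:
                    intervals.append((f.fill_date, f.fill_date + f.days_supply))
            exposure[group] = intervals
    return exposure


def build_state_timeline(
    patient_id: str,
    exposure: dict[int, list[tuple[int, int]]],
    study_end: int,
) -> StateTimeline:
    """Sweep exposure intervals into maximal constant-state segments.

    The timeline covers ``[0, study_end)``; days with no active exposure
    are in state zero.  Every patient therefore starts in state zero
    unless a fill is active on day 0.
    """
    cuts = {0, study_end}
    for intervals in exposure.values():
        for start, end in intervals:
            if start < study_end:
                cuts.add(max(start, 0))
            if end < study_end:
                cuts.add(max(end, 0))
    points = sorted(cuts)

    segments: list[tuple[int, int, int]] = []
    for left, right in zip(points, points[1:]):
        mask = 0
        for group, intervals in exposure.items():
            for start, end in intervals:
                if start <= left < end:
                    mask |= group
                    break
        if segments and segments[-1][0] == mask:
            segments[-1] = (mask, segments[-1][1], right)
        else:
            segments.append((mask, left, right))
    return StateTimeline(patient_id, [(m, s, e) for m, s, e in segments])


# ---------------------------------------------------------------------------
# Transitions and responsible-physician attribution
# ---------------------------------------------------------------------------

def assign_responsible_physician(
    fills: Sequence[FillEvent],
    date: int,
    added_mask: int,
    removed_mask: int,
) -> tuple[str, bool]:
    """Attribute a state change at ``date`` to a prescriber.

    Additions are attributed to the prescriber of the triggering fill (the
    fill of an added group starting on the transition date); when several
    groups are added simultaneously by different prescribers the priority
    order O > B > S selects the fill and the record is flagged ambiguous.
    A pure lapse (removal only) is attributed to the patient's most recent
    prescriber at or before the transition date, since stopping a drug
    triggers no claim of its own.

    Returns ``(physician_id, ambiguous)``.
    """
    if added_mask:
        prescribers: list[str] = []
        chosen: str | None = None
        for group in GROUPS:  # O > B > S priority
            if not added_mask & group:
                continue
            candidates = sorted(
                (f for f in fills if f.drug_group == group and f.fill_date == date),
                key=lambda f: (-f.days_supply, f.prescriber_id),
            )
            if not candidates:
                raise AttributionError(
                    f"no fill of group {GROUP_LETTERS[group]} on day {date} "
                    f"matches the addition (inconsistent timeline)"
                )
            if chosen is None:
                chosen = candidates[0].prescriber_id
            prescribers.extend(f.prescriber_id for f in candidates)
        ambiguous = len(set(prescribers)) > 1
        assert chosen is not None
        return chosen, ambiguous

    if not removed_mask:
        raise AttributionError("transition with no added or removed groups")
    past = [f for f in fills if f.fill_date <= date]
    if not past:
        raise AttributionError(f"lapse at day {date} with no prior fill")
    # Most recent fill; ties broken by O > B > S then prescriber id.
    best = max(
        past,
        key=lambda f: (f.fill_date, -GROUPS.index(f.drug_group), f.prescriber_id),
    )
    same_day = {
        f.prescriber_id for f in past if f.fill_date == best.fill_date
    }
    return best.prescriber_id, len(same_day) > 1


def enumerate_transitions(
    timeline: StateTimeline, fills: Sequence[FillEvent]
) -> list[TransitionRecord]:
    """One record per boundary between adjacent timeline segments.

    Patients are taken to start in state zero, so a timeline whose first
    segment is a non-zero state beginning on day 0 contributes an initial
    ``zero -> state`` transition dated day 0.
    """
    records: list[TransitionRecord] = []
    segs = timeline.segments
    if not segs:
        return records

    boundaries: list[tuple[int, int, int]] = []  # (from_mask, to_mask, date)
    first_mask, first_start, _ = segs[0]
    if first_mask != 0 and first_start == 0:
        boundaries.append((0, first_mask, 0))
    for (m1, _, e1), (m2, s2, _) in zip(segs, segs[1:]):
        boundaries.append((m1, m2, s2))

    for t, (from_mask, to_mask, date) in enumerate(boundaries):
        added = to_mask & ~from_mask
        removed = from_mask & ~to_mask
        phys, ambiguous = assign_responsible_physician(fills, date, added, removed)
        records.append(
            TransitionRecord(
                patient_id=timeline.patient_id,
                t_index=t,
                from_mask=from_mask,
                to_mask=to_mask,
                date=date,
                responsible_physician_id=phys,
                ambiguous=ambiguous,
            )
        )
    return records


def count_transition_matrix(records: Iterable[TransitionRecord]) -> TransitionMatrix:
    """Pool transition records into counts ``C[i, j]`` and probabilities.

    ``pi[i, j] = C[i, j] / sum_j C[i, j]``; rows without observed
    transitions are undefined (NaN) rather than zero-filled.
    """
    counts = np.zeros((8, 8), dtype=np.int64)
    for r in records:
        counts[state_index(r.from_mask), state_index(r.to_mask)] += 1
    row_sums = counts.sum(axis=1)
    defined = row_sums > 0
    probs = np.full((8, 8), np.nan)
    probs[defined] = counts[defined] / row_sums[defined, None]
    return TransitionMatrix(counts=counts, probabilities=probs, defined_rows=defined)


# ---------------------------------------------------------------------------
# Stage-specific record extraction
# ---------------------------------------------------------------------------

def obs_duration_records(
    timeline: StateTimeline,
    transitions: Sequence[TransitionRecord],
    study_end: int,
) -> list[dict]:
    """Censored time-in-OBS spells for the discontinuation model.

    One record per maximal OBS segment; a spell still active at the end of
    follow-up is censored.  The responsible physician is the one who
    brought the patient into OBS (the attribution of the entering
    transition).
    """
    entering = {
        r.date: r for r in transitions if r.to_mask == OBS_MASK
    }
    out = []
    for mask, start, end in timeline.segments:
        if mask != OBS_MASK:
            continue
        enter = entering.get(start)
        if enter is None:
            raise AttributionError(
                f"OBS spell at day {start} for patient {timeline.patient_id} "
                f"has no entering transition"
            )
        out.append(
            {
                "patient_id": timeline.patient_id,
                "entry_date": start,
                "duration_days": end - start,
                "censored": end == study_end,
                "responsible_physician_id": enter.responsible_physician_id,
            }
        )
    return out


def opioid_focus_records(
    records: Iterable[TransitionRecord],
) -> list[tuple[TransitionRecord, int]]:
    """Transitions from the opioids-only state to risky states or to zero.

    Keeps ``O -> {OB, OS, OBS}`` (outcome 1, risky) and ``O -> zero``
    (outcome 0).  Sideways moves such as ``O -> B`` are excluded: they are
    neither a risky combination nor a return to the clean state.
    """
    keep = {0: 0, O | B: 1, O | S: 1, OBS_MASK: 1}
    out = []
    for r in records:
        if r.from_mask == O and r.to_mask in keep:
            out.append((r, keep[r.to_mask]))
    return out


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def analyze_patient(
    patient_id: str,
    fills: Sequence[FillEvent],
    study_end: int,
    mode: str = "union",
) -> tuple[StateTimeline, list[TransitionRecord], list[dict]]:
    """Timeline, transitions, and OBS spells for one patient's fills."""
    exposure = fills_to_exposure(fills, mode=mode)
    timeline = build_state_timeline(patient_id, exposure, study_end)
    transitions = enumerate_transitions(timeline, fills)
    durations = obs_duration_records(timeline, transitions, study_end)
    return timeline, transitions, durations


def _frame_to_fills(fills_df: pd.DataFrame) -> dict[str, list[FillEvent]]:
    by_patient: dict[str, list[FillEvent]] = {}
    for row in fills_df.itertuples(index=False):
        group = row.drug_group
        if isinstance(group, str):
            group = LETTER_GROUPS[group]
        by_patient.setdefault(str(row.patient_id), []).append(
            FillEvent(
                patient_id=str(row.patient_id),
                prescriber_id=str(row.prescriber_id),
                drug_group=group,
                fill_date=int(row.fill_date),
                days_supply=int(row.days_supply),
            )
        )
    return by_patient


def analyze_cohort(
    fills_df: pd.DataFrame, study_end: int, mode: str = "union"
) -> dict:
    """Run the state pipeline for every patient with at least one fill.

    Patients absent from the fill log are outside the analysis cohort (the
    cohort requires at least one fill).  Returns timelines, pooled
    transition records, the 8x8 matrix, and OBS duration records.
    """
    by_patient = _frame_to_fills(fills_df)
    timelines: dict[str, StateTimeline] = {}
    transitions: list[TransitionRecord] = []
    durations: list[dict] = []
    for pid in sorted(by_patient):
        fills = sorted(by_patient[pid], key=lambda f: (f.fill_date, f.prescriber_id))
        timeline, recs, durs = analyze_patient(pid, fills, study_end, mode=mode)
        timelines[pid] = timeline
        transitions.extend(recs)
        durations.extend(durs)
    matrix = count_transition_matrix(transitions)
    return {
        "timelines": timelines,
        "transitions": transitions,
        "matrix": matrix,
        "durations": durations,
        "n_ambiguous": sum(r.ambiguous for r in transitions),
    }


def transitions_to_frame(records: Sequence[TransitionRecord]) -> pd.DataFrame:
    """Tabular view of transition records (one row per state change)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "t_index": [r.t_index for r in records],
            "from_state": [state_name(r.from_mask) for r in records],
            "to_state": [state_name(r.to_mask) for r in records],
            "from_mask": [r.from_mask for r in records],
            "to_mask": [r.to_mask for r in records],
            "drug_count_from": [r.drug_count_from for r in records],
            "drug_count_to": [r.drug_count_to for r in records],
            "date": [r.date for r in records],
            "responsible_physician_id": [r.responsible_physician_id for r in records],
            "ambiguous": [r.ambiguous for r in records],
        }
    )
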
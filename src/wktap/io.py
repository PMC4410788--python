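"""Tap-log and cohort file handling.

A tapping session is a flat record of timestamped events captured from a
response pad during one run of the synchronization-continuation paradigm:
tone onsets ("stimulus" events) and finger taps ("tap" events).  Sessions
are interchanged as plain CSV so that they are auditable with any
spreadsheet or shell tool.

Tap log
    header ``participant_id,group,condition,event_type,time_ms`` with one
    event per row.  ``condition`` is ``externally_paced`` or ``self_paced``,
    ``event_type`` is ``stimulus`` or ``tap`` and ``time_ms`` is a
    non-negative time in milliseconds, stored at 0.1 ms granularity.

Cohort table
    header ``participant_id,group,age,gender[,stroop_interference_s,
    digit_span_backwards]``.  Cognitive scores are optional and may be
    blank (missing), never zero-filled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

EXTERNALLY_PACED = "externally_paced"
SELF_PACED = "self_paced"
CONDITIONS = (EXTERNALLY_PACED, SELF_PACED)

EVENT_STIMULUS = "stimulus"
EVENT_TAP = "tap"
EVENT_TYPES = (EVENT_STIMULUS, EVENT_TAP)

GENDERS = ("M", "F")

TAP_LOG_COLUMNS = ["participant_id", "group", "condition", "event_type", "time_ms"]
COHORT_REQUIRED = ["participant_id", "group", "age", "gender"]
COHORT_SCORES = ["stroop_interference_s", "digit_span_backwards"]

#: serialization granularity for times, in ms
TIME_DECIMALS = 1


class TapLogError(ValueError):
    """Malformed tap-log file or invalid session."""


class CohortError(ValueError):
    """Malformed cohort file."""


@dataclass
class TapSession:
    """One participant x condition recording.

    ``stimulus_onsets_ms`` are the tone onsets (all 50 for the
    externally-paced task, the 6 pacing tones for the self-paced task);
    ``tap_times_ms`` are every recorded tap, including taps made during
    the self-paced synchronization phase.
    """

    participant_id: str
    group: str
    condition: str
    stimulus_onsets_ms: np.ndarray
    tap_times_ms: np.ndarray
    target_interval_ms: float = 1500.0

    def __post_init__(self) -> None:
        self.stimulus_onsets_ms = np.asarray(self.stimulus_onsets_ms, dtype=float)
        self.tap_times_ms = np.asarray(self.tap_times_ms, dtype=float)
        if self.condition not in CONDITIONS:
            raise TapLogError(f"unknown condition {self.condition!r}")
        for name, arr in (("stimulus_onsets_ms", self.stimulus_onsets_ms),
                          ("tap_times_ms", self.tap_times_ms)):
            if arr.size and not np.all(np.isfinite(arr)):
                raise TapLogError(f"{name}: non-finite time in session "
                                  f"{self.participant_id}/{self.condition}")
            if arr.size and arr.min() < 0:
                raise TapLogError(f"{name}: negative time in session "
                                  f"{self.participant_id}/{self.condition}")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise TapLogError(f"{name}: times not strictly increasing in "
                                  f"session {self.participant_id}/{self.condition}")
        if self.target_interval_ms <= 0:
            raise TapLogError("target_interval_ms must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TapSession):
            return NotImplemented
        return (self.participant_id == other.participant_id
                and self.group == other.group
                and self.condition == other.condition
                and self.target_interval_ms == other.target_interval_ms
                and np.array_equal(self.stimulus_onsets_ms, other.stimulus_onsets_ms)
                and np.array_equal(self.tap_times_ms, other.tap_times_ms))


def _parse_time(raw: str, line: int) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise TapLogError(f"line {line}: non-numeric time_ms {raw!r}") from None
    if not np.isfinite(value) or value < 0:
        raise TapLogError(f"line {line}: time_ms must be finite and >= 0, got {raw!r}")
    return value


def read_tap_log(path: str | Path) -> list[TapSession]:
    """Read a tap-log CSV into validated sessions.

    Returns one :class:`TapSession` per (participant, condition) pair,
    sorted by participant then condition, with event times sorted
    ascending.  A header-only file yields an empty list.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TAP_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TapLogError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        return []

    # file line numbers: header is line 1
    lines = df.index.to_numpy() + 2
    times = np.array([_parse_time(raw, line)
                      for raw, line in zip(df["time_ms"], lines)])
    for col, allowed in (("condition", CONDITIONS), ("event_type", EVENT_TYPES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            line = lines[bad.to_numpy()][0]
            raise TapLogError(f"line {line}: invalid {col} {df[col][bad].iloc[0]!r}")

    work = df.assign(time_ms=times)
    dup = work.duplicated(subset=["participant_id", "condition", "event_type", "time_ms"])
    if dup.any():
        line = lines[dup.to_numpy()][0]
        raise TapLogError(f"line {line}: duplicate event "
                          "(participant, condition, event_type, time)")
    groups_per_pid = work.groupby("participant_id")["group"].nunique()
    if (groups_per_pid > 1).any():
        pid = groups_per_pid[groups_per_pid > 1].index[0]
        raise TapLogError(f"participant {pid!r} appears with more than one group label")

    sessions = []
    for (pid, cond), chunk in sorted(work.groupby(["participant_id", "condition"]),
                                     key=lambda kv: kv[0]):
        onsets = np.sort(chunk.loc[chunk.event_type == EVENT_STIMULUS, "time_ms"].to_numpy())
        taps = np.sort(chunk.loc[chunk.event_type == EVENT_TAP, "time_ms"].to_numpy())
        sessions.append(TapSession(participant_id=pid, group=chunk["group"].iloc[0],
                                   condition=cond, stimulus_onsets_ms=onsets,
                                   tap_times_ms=taps))
    return sessions


def write_tap_log(sessions: Iterable[TapSession], path: str | Path) -> Path:
    """Write sessions to CSV with deterministic row order.

    Rows are ordered by (participant, condition, time), stimulus before tap
    on equal times; times are serialized at 0.1 ms granularity.
    """
    path = Path(path)
    rows = []
    for s in sorted(sessions, key=lambda s: (s.participant_id, s.condition)):
        events = ([(t, EVENT_STIMULUS) for t in s.stimulus_onsets_ms]
                  + [(t, EVENT_TAP) for t in s.tap_times_ms])
        events.sort()
        rows.extend(f"{s.participant_id},{s.group},{s.condition},{etype},{t:.{TIME_DECIMALS}f}"
                    for t, etype in events)
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(TAP_LOG_COLUMNS) + "\n")
        fh.write("".join(r + "\n" for r in rows))
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Returns a DataFrame with columns ``participant_id`` (str), ``group``
    (str), ``age`` (float, > 0), ``gender`` (``M``/``F``) and any of the
    optional score columns present in the file as floats with NaN for
    blanks.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing column(s) {', '.join(missing)}")
    lines = df.index.to_numpy() + 2

    dup = df.duplicated(subset=["participant_id"])
    if dup.any():
        pid = df.loc[dup, "participant_id"].iloc[0]
        raise CohortError(f"duplicate participant_id {pid!r}")

    ages = []
    for raw, line in zip(df["age"], lines):
        try:
            age = float(raw)
        except (TypeError, ValueError):
            raise CohortError(f"line {line}: non-numeric age {raw!r}") from None
        if not np.isfinite(age) or age <= 0:
            raise CohortError(f"line {line}: age must be > 0, got {raw!r}")
        ages.append(age)

    bad_gender = ~df["gender"].isin(GENDERS)
    if bad_gender.any():
        line = lines[bad_gender.to_numpy()][0]
        raise CohortError(f"line {line}: unknown gender code "
                          f"{df['gender'][bad_gender].iloc[0]!r} (use M or F)")

    out = pd.DataFrame({
        "participant_id": df["participant_id"].astype(str),
        "group": df["group"].astype(str),
        "age": ages,
        "gender": df["gender"].astype(str),
    })
    for col in COHORT_SCORES:
        if col in df.columns:
            vals = []
            for raw, line in zip(df[col], lines):
                raw = raw.strip()
                if raw == "":
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(raw))
                except ValueError:
                    raise CohortError(f"line {line}: non-numeric {col} {raw!r}") from None
            out[col] = vals
    return out


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table to CSV deterministically (sorted by participant)."""
    path = Path(path)
    cols = COHORT_REQUIRED + [c for c in COHORT_SCORES if c in cohort.columns]
    out = cohort[cols].sort_values("participant_id", kind="stable")
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for _, row in out.iterrows():
            cells = [str(row["participant_id"]), str(row["group"]),
                     f"{row['age']:.1f}", str(row["gender"])]
            for col in cols[4:]:
                v = row[col]
                cells.append("" if pd.isna(v) else f"{v:.1f}")
            fh.write(",".join(cells) + "\n")
    return path
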
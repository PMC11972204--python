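"""Events tables: the package-wide representation of stimulus and percept streams.

Events are plain :class:`pandas.DataFrame` objects in a BIDS-events dialect
with columns ``onset`` (s, 0-based), ``duration`` (s), ``trial_type`` and
``source``.  ``source`` distinguishes experimenter-controlled stimulus blocks
(``"stimulus"``) from subject-reported percept episodes (``"percept"``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

#: Closed set of block / percept labels.
CONDITIONS = ("fixation", "horizontal", "vertical", "flicker", "ambiguous")
SOURCES = ("stimulus", "percept")
EVENT_COLUMNS = ("onset", "duration", "trial_type", "source")


class EventTableError(ValueError):
    """Raised when an events table violates its invariants."""


def make_events(rows: Iterable[Sequence]) -> pd.DataFrame:
    """Build an events table from ``(onset, duration, trial_type, source)`` rows."""
    df = pd.DataFrame(list(rows), columns=list(EVENT_COLUMNS))
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    validate_events(df)
    return df


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check events-table invariants; return the table unchanged if valid.

    Invariants: required columns present; durations strictly positive; labels
    from the closed condition/source sets; onsets non-decreasing and events
    non-overlapping within each source.
    """
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise EventTableError(f"events table missing columns: {sorted(missing)}")
    if len(events) == 0:
        return events
    if (events["duration"] <= 0).any():
        bad = events.loc[events["duration"] <= 0]
        raise EventTableError(f"non-positive durations at rows {list(bad.index)}")
    bad_cond = set(events["trial_type"]) - set(CONDITIONS)
    if bad_cond:
        raise EventTableError(f"unknown trial_type labels: {sorted(bad_cond)}")
    bad_src = set(events["source"]) - set(SOURCES)
    if bad_src:
        raise EventTableError(f"unknown source labels: {sorted(bad_src)}")
    for src, grp in events.groupby("source"):
        onsets = grp["onset"].to_numpy()
        ends = onsets + grp["duration"].to_numpy()
        if (onsets[1:] < onsets[:-1]).any():
            raise EventTableError(f"onsets not sorted within source {src!r}")
        # tolerate float jitter at block boundaries
        if (onsets[1:] - ends[:-1] < -1e-9).any():
            raise EventTableError(f"overlapping events within source {src!r}")
    return events


def events_of_source(events: pd.DataFrame, source: str) -> pd.DataFrame:
    if source not in SOURCES:
        raise EventTableError(f"unknown source {source!r}")
    return events.loc[events["source"] == source].reset_index(drop=True)
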
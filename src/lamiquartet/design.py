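"""Stimulus schedules and percept streams for the motion quartet.

The motion quartet shows two diagonally opposed inducer pairs in alternation;
depending on the timing this is seen either as unambiguous ("physical")
horizontal/vertical motion or, for the ambiguous version, as a bistable
percept that spontaneously alternates between the two axes.  This module
builds the frame-accurate block schedules for both run types and samples
stochastic percept-report streams for the ambiguous condition.

Block scheme of one run (defaults): 20 s fixation, then six repetitions of
[4 alternations of 10 s horizontal + 10 s vertical motion (80 s) followed by
16 s flicker baseline], then 20 s fixation — 616 s, i.e. 308 volumes at
TR = 2 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from lamiquartet.events import EventTableError, events_of_source, make_events


class InvalidTimingError(ValueError):
    """Frame counts or refresh rate outside their valid domain."""


class InvalidScheduleError(ValueError):
    """Block durations or repetition counts outside their valid domain."""


class InvalidProcessError(ValueError):
    """Percept-switch process parameters outside their valid domain."""


@lru_cache(maxsize=32)
def _frozen_gamma(shape: float, scale: float):
    return stats.gamma(a=shape, scale=scale)


@dataclass(frozen=True)
class StimulusTiming:
    """Frame timing of the ambiguous quartet display.

    Defaults reproduce a 60 Hz display showing each inducer pair for 9 frames
    (150 ms) separated by 4 blank frames (~67 ms); one full apparent-motion
    cycle contains two pair presentations.
    """

    refresh_hz: float = 60.0
    pair_on_frames: int = 9
    isi_frames: int = 4
    pairs_per_cycle: int = 2

    def __post_init__(self) -> None:
        if self.refresh_hz <= 0:
            raise InvalidTimingError(f"refresh_hz must be positive, got {self.refresh_hz}")
        for name in ("pair_on_frames", "isi_frames", "pairs_per_cycle"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise InvalidTimingError(f"{name} must be a positive integer, got {value!r}")

    @property
    def pair_on_ms(self) -> float:
        """Pair presentation time in milliseconds."""
        return 1000.0 * self.pair_on_frames / self.refresh_hz

    @property
    def isi_ms(self) -> float:
        """Inter-stimulus interval in milliseconds."""
        return 1000.0 * self.isi_frames / self.refresh_hz


def cycle_frequency(timing: StimulusTiming, ndigits: int | None = None) -> float:
    """Apparent-motion cycle frequency in Hz.

    ``refresh_hz / (pairs_per_cycle * (pair_on_frames + isi_frames))``;
    with ``ndigits`` the result is rounded (half-to-even) for display, the
    convention under which the default timing prints as 2.3 Hz.
    """
    freq = timing.refresh_hz / (timing.pairs_per_cycle * (timing.pair_on_frames + timing.isi_frames))
    return round(freq, ndigits) if ndigits is not None else freq


@dataclass(frozen=True)
class RunSchedule:
    """Ordered block sequence of one run plus its sampling grid."""

    blocks: tuple[tuple[str, float], ...]
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise InvalidScheduleError(f"tr_s must be positive, got {self.tr_s}")
        for cond, dur in self.blocks:
            if dur <= 0:
                raise InvalidScheduleError(f"non-positive block duration {dur} for {cond!r}")

    @property
    def total_s(self) -> float:
        return float(sum(d for _, d in self.blocks))

    @property
    def n_volumes(self) -> int:
        """Whole volumes fitting into the run (floor of total / TR)."""
        return int(np.floor(self.total_s / self.tr_s + 1e-9))


def _schedule_blocks(
    motion_conditions: tuple[str, ...],
    block_s: float,
    n_alternations: int,
    flicker_s: float,
    n_repetitions: int,
    fixation_s: float,
    fixation_end: bool,
) -> list[tuple[str, float]]:
    blocks: list[tuple[str, float]] = []
    if fixation_s > 0:
        blocks.append(("fixation", fixation_s))
    for _ in range(n_repetitions):
        for _ in range(n_alternations):
            for cond in motion_conditions:
                blocks.append((cond, block_s))
        blocks.append(("flicker", flicker_s))
    if fixation_s > 0 and fixation_end:
        blocks.append(("fixation", fixation_s))
    return blocks


def _events_from_blocks(blocks: list[tuple[str, float]]) -> pd.DataFrame:
    rows, t = [], 0.0
    for cond, dur in blocks:
        rows.append((t, dur, cond, "stimulus"))
        t += dur
    return make_events(rows)


def build_physical_schedule(
    block_s: float = 10.0,
    flicker_s: float = 16.0,
    n_repetitions: int = 6,
    n_alternations: int = 4,
    fixation_s: float = 20.0,
    fixation_end: bool = True,
    tr_s: float = 2.0,
) -> tuple[RunSchedule, pd.DataFrame]:
    """Physical motion-quartet run: alternating H/V blocks with flicker baseline.

    Each repetition holds ``n_alternations`` horizontal+vertical pairs
    (4 × 20 s = 80 s by default) followed by a flicker block; fixation
    bookends the run at both ends by default.
    """
    if n_repetitions < 1 or n_alternations < 1:
        raise InvalidScheduleError("n_repetitions and n_alternations must be >= 1")
    blocks = _schedule_blocks(
        ("horizontal", "vertical"), block_s, n_alternations, flicker_s, n_repetitions, fixation_s, fixation_end
    )
    return RunSchedule(tuple(blocks), tr_s), _events_from_blocks(blocks)


def build_ambiguous_schedule(
    ambiguous_s: float = 80.0,
    flicker_s: float = 16.0,
    n_repetitions: int = 6,
    fixation_s: float = 20.0,
    fixation_end: bool = True,
    tr_s: float = 2.0,
) -> tuple[RunSchedule, pd.DataFrame]:
    """Ambiguous run: same scheme as the physical run with each 80 s motion
    super-block replaced by one continuous ambiguous-quartet block."""
    if n_repetitions < 1:
        raise InvalidScheduleError("n_repetitions must be >= 1")
    blocks = _schedule_blocks(("ambiguous",), ambiguous_s, 1, flicker_s, n_repetitions, fixation_s, fixation_end)
    return RunSchedule(tuple(blocks), tr_s), _events_from_blocks(blocks)


@dataclass(frozen=True)
class PerceptProcess:
    """Stochastic percept-switch process for the ambiguous condition.

    Dwell times (episode durations) are i.i.d. from a gamma law with mean
    ``mean_dwell_s`` and shape ``shape``, truncated to
    ``[min_dwell_s, max_dwell_s]``; successive percepts strictly alternate
    between horizontal and vertical.  ``report_lag_s`` shifts reported onsets
    by a constant motor latency (0 by default).
    """

    min_dwell_s: float = 3.0
    max_dwell_s: float = 20.0
    mean_dwell_s: float = 6.0
    shape: float = 3.0
    report_lag_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.min_dwell_s < self.max_dwell_s):
            raise InvalidProcessError(
                f"need 0 < min_dwell_s < max_dwell_s, got [{self.min_dwell_s}, {self.max_dwell_s}]"
            )
        if self.mean_dwell_s <= 0 or self.shape <= 0:
            raise InvalidProcessError("mean_dwell_s and shape must be positive")

    @property
    def _gamma(self):
        return _frozen_gamma(self.shape, self.mean_dwell_s / self.shape)

    def truncated_mean(self) -> float:
        """Mean dwell of the truncated law, by numerical integration."""
        g = self._gamma
        lo, hi = self.min_dwell_s, self.max_dwell_s
        z = g.cdf(hi) - g.cdf(lo)
        from scipy.integrate import quad

        num, _ = quad(lambda x: x * g.pdf(x), lo, hi, limit=200)
        return num / z

    def truncated_var(self) -> float:
        g = self._gamma
        lo, hi = self.min_dwell_s, self.max_dwell_s
        z = g.cdf(hi) - g.cdf(lo)
        from scipy.integrate import quad

        m = self.truncated_mean()
        num, _ = quad(lambda x: (x - m) ** 2 * g.pdf(x), lo, hi, limit=200)
        return num / z

    def sample_dwells(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` dwell times by inverse-CDF sampling of the truncated gamma."""
        g = self._gamma
        lo, hi = g.cdf(self.min_dwell_s), g.cdf(self.max_dwell_s)
        u = rng.uniform(lo, hi, size=n)
        return np.asarray(g.ppf(u))


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_percept_stream(
    process: PerceptProcess,
    total_s: float,
    seed: int | np.random.Generator,
    t0_s: float = 0.0,
) -> pd.DataFrame:
    """Sample an alternating horizontal/vertical percept stream covering
    ``[t0_s, t0_s + total_s]``.

    The first percept is chosen at random; the last episode is clipped at the
    end of the interval.  Deterministic given the seed.
    """
    if total_s <= 0:
        raise InvalidProcessError(f"total_s must be positive, got {total_s}")
    rng = _as_rng(seed)
    first = int(rng.integers(0, 2))
    rows = []
    t = 0.0
    k = 0
    pending: list[float] = []
    while t < total_s:
        if not pending:  # draw dwells in batches for speed
            pending = list(process.sample_dwells(16, rng))
        dwell = float(min(pending.pop(0), total_s - t))
        cond = ("horizontal", "vertical")[(first + k) % 2]
        rows.append((t0_s + t + process.report_lag_s, dwell, cond, "percept"))
        t += dwell
        k += 1
    return make_events(rows)


def percept_stream_for_run(
    schedule_events: pd.DataFrame,
    process: PerceptProcess,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Sample an independent percept stream inside each ambiguous block of a run."""
    rng = _as_rng(seed)
    amb = schedule_events.loc[schedule_events["trial_type"] == "ambiguous"]
    if len(amb) == 0:
        raise InvalidScheduleError("run contains no ambiguous blocks")
    parts = [
        sample_percept_stream(process, row.duration, rng, t0_s=row.onset)
        for row in amb.itertuples()
    ]
    return pd.concat(parts, ignore_index=True)


def screen_switch_rate(events: pd.DataFrame, window_s: float = 5.0) -> bool:
    """Pre-scan screening rule: pass iff every percept episode lasts at most
    ``window_s`` seconds, i.e. a switch occurs at least once every ``window_s``
    seconds (boundary inclusive)."""
    percepts = events_of_source(events, "percept")
    if len(percepts) == 0:
        raise EventTableError("screening undefined on an empty percept table")
    return bool((percepts["duration"].to_numpy() <= window_s + 1e-12).all())


def with_lag(process: PerceptProcess, lag_s: float) -> PerceptProcess:
    """Copy of ``process`` with a different report latency."""
    return replace(process, report_lag_s=lag_s)
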
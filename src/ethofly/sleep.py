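"""DAM activity and sleep architecture.

Infrared beam-break counts are binned (30 s by default) and aligned to
zeitgeber time (ZT; hours since lights-on) under a 12:12 light:dark cycle.
Fly sleep follows the standard convention: any maximal run of zero-count
bins spanning at least 5 minutes is a sleep bout.  Six metrics are computed
separately for day (ZT0-12) and night (ZT12-24) and averaged over recording
days: total activity, total sleep, activity while awake, sleep latency,
sleep bout count, and mean sleep bout duration.

Bouts that span the day/night boundary are handled in two different ways on
purpose: sleep *minutes* are attributed to each phase by overlap, which keeps
total sleep conserved (day + night sleep = whole-day sleep), while the *bout*
itself (for count, duration, and latency) belongs to the phase in which it
started.  Bout-duration statistics use the bout's minutes inside the phase,
so the per-phase identity ``bout_count * mean_bout_duration`` equals the
phase's sleep attributable to bouts that started there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ActivitySeries",
    "SleepBout",
    "PhaseMetrics",
    "FlyPhaseMetrics",
    "SLEEP_THRESHOLD_MIN",
    "detect_sleep",
    "phase_metrics",
    "profile_curve",
    "fly_metrics_table",
    "exclude_dead",
]

SLEEP_THRESHOLD_MIN = 5.0
DAY_MIN = 1440
PHASE_MIN = 720  # each of day and night lasts ZT 12 h


@dataclass
class ActivitySeries:
    """Binned beam-break counts for one fly, aligned to zeitgeber time."""

    fly_id: str
    genotype: str
    counts: np.ndarray
    bin_seconds: int = 30
    start_zt_hours: float = 0.0
    missing: np.ndarray | None = None  # True where a bin was absent in the raw file

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if 300 % self.bin_seconds != 0:
            raise ValueError("bin duration must divide 300 s (5-min sleep rule)")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.counts.shape:
                raise ValueError("missing mask must match counts length")

    @property
    def bins_per_day(self) -> int:
        return 86400 // self.bin_seconds

    @property
    def n_complete_days(self) -> int:
        return self.counts.size // self.bins_per_day


@dataclass(frozen=True)
class SleepBout:
    """A maximal inactivity run of at least 5 minutes."""

    start_min: float  # minutes since recording start (ZT-referenced)
    duration_min: float
    day_index: int
    phase_at_onset: str  # "day" | "night"


@dataclass(frozen=True)
class PhaseMetrics:
    total_activity: float  # beam-break counts per phase
    total_sleep_min: float
    activity_while_awake: float  # counts per awake minute
    sleep_latency_min: float
    bout_count: float
    mean_bout_duration_min: float


@dataclass(frozen=True)
class FlyPhaseMetrics:
    fly_id: str
    genotype: str
    n_days: int
    day: PhaseMetrics
    night: PhaseMetrics


def _phase_of(zt_min: float) -> str:
    return "day" if (zt_min % DAY_MIN) < PHASE_MIN else "night"


def detect_sleep(
    series: ActivitySeries,
    threshold_min: float = SLEEP_THRESHOLD_MIN,
    missing_breaks_runs: bool = True,
) -> tuple[np.ndarray, list[SleepBout]]:
    """Find sleep bins and maximal sleep bouts.

    A bin is asleep iff it belongs to a maximal run of zero-count bins whose
    total duration is at least ``threshold_min`` minutes (>= 10 bins at 30 s).
    Missing bins break candidate runs by default, so gaps never fabricate
    sleep; pass ``missing_breaks_runs=False`` to bridge them.
    """
    counts = series.counts
    bin_min = series.bin_seconds / 60.0
    min_bins = int(round(threshold_min / bin_min))
    inactive = counts == 0
    if missing_breaks_runs and series.missing is not None:
        inactive &= ~series.missing
    # maximal run boundaries
    padded = np.concatenate(([False], inactive, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    sleep = np.zeros(counts.size, dtype=bool)
    bouts: list[SleepBout] = []
    offset_min = series.start_zt_hours * 60.0
    for s, e in zip(starts, ends):
        if e - s < min_bins:
            continue
        sleep[s:e] = True
        start_min = offset_min + s * bin_min
        bouts.append(
            SleepBout(
                start_min=start_min,
                duration_min=(e - s) * bin_min,
                day_index=int(start_min // DAY_MIN),
                phase_at_onset=_phase_of(start_min),
            )
        )
    return sleep, bouts


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def phase_metrics(
    series: ActivitySeries,
    sleep: np.ndarray | None = None,
    bouts: list[SleepBout] | None = None,
) -> FlyPhaseMetrics:
    """Six day/night metrics per fly, averaged over complete recording days.

    Requires the recording to start at ZT0.  An incomplete trailing day is
    excluded from the averages with a warning.
    """
    if series.start_zt_hours % 24 != 0:
        raise ValueError("phase metrics require a recording starting at ZT0")
    if sleep is None or bouts is None:
        sleep, bouts = detect_sleep(series)
    n_days = series.n_complete_days
    if n_days < 1:
        raise ValueError("need at least one complete recording day")
    if series.counts.size % series.bins_per_day != 0:
        warnings.warn(
            "incomplete final day excluded from day-averaged metrics",
            stacklevel=2,
        )
    bin_min = series.bin_seconds / 60.0
    per_phase: dict[str, list[PhaseMetrics]] = {"day": [], "night": []}
    for d in range(n_days):
        for phase, zt0 in (("day", 0.0), ("night", float(PHASE_MIN))):
            p_start = d * DAY_MIN + zt0
            p_end = p_start + PHASE_MIN
            b0 = int(round(p_start / bin_min))
            b1 = int(round(p_end / bin_min))
            total_activity = float(series.counts[b0:b1].sum())
            sleep_min = float(sleep[b0:b1].sum()) * bin_min
            awake_min = PHASE_MIN - sleep_min
            awa = total_activity / awake_min if awake_min > 0 else 0.0
            onset_bouts = [
                b
                for b in bouts
                if p_start <= b.start_min < p_end
            ]
            if sleep[b0] and any(
                b.start_min < p_start < b.start_min + b.duration_min for b in bouts
            ):
                latency = 0.0  # already asleep at phase start
            elif onset_bouts:
                latency = onset_bouts[0].start_min - p_start
            else:
                latency = float(PHASE_MIN)
            in_phase = [
                _overlap(b.start_min, b.start_min + b.duration_min, p_start, p_end)
                for b in onset_bouts
            ]
            count = len(onset_bouts)
            mean_dur = sum(in_phase) / count if count else 0.0
            per_phase[phase].append(
                PhaseMetrics(total_activity, sleep_min, awa, latency, count, mean_dur)
            )

    def _avg(ms: list[PhaseMetrics]) -> PhaseMetrics:
        return PhaseMetrics(
            *(float(np.mean([getattr(m, f) for m in ms])) for f in PhaseMetrics.__dataclass_fields__)
        )

    return FlyPhaseMetrics(
        fly_id=series.fly_id,
        genotype=series.genotype,
        n_days=n_days,
        day=_avg(per_phase["day"]),
        night=_avg(per_phase["night"]),
    )


def fly_metrics_table(series_list: list[ActivitySeries]) -> pd.DataFrame:
    """Tidy per-fly metrics: one row per fly x phase."""
    rows = []
    for s in series_list:
        m = phase_metrics(s)
        for phase in ("day", "night"):
            pm: PhaseMetrics = getattr(m, phase)
            rows.append(
                dict(
                    fly_id=m.fly_id,
                    genotype=m.genotype,
                    phase=phase,
                    total_activity=pm.total_activity,
                    total_sleep_min=pm.total_sleep_min,
                    activity_while_awake=pm.activity_while_awake,
                    sleep_latency_min=pm.sleep_latency_min,
                    bout_count=pm.bout_count,
                    mean_bout_duration_min=pm.mean_bout_duration_min,
                )
            )
    return pd.DataFrame(rows)


def profile_curve(
    series_list: list[ActivitySeries], window_min: int = 30
) -> pd.DataFrame:
    """Mean activity and sleep per ZT window, averaged over flies and days.

    Returns one row per window (48 per day at the default 30 min) with the
    mean summed counts and mean sleep minutes in that window.
    """
    if not series_list:
        raise ValueError("empty group")
    bin_min = series_list[0].bin_seconds / 60.0
    if window_min % (series_list[0].bin_seconds / 60) != 0:
        raise ValueError("window must be a multiple of the bin duration")
    per_win = int(round(window_min / bin_min))
    n_win = DAY_MIN // window_min
    act = np.zeros(n_win)
    slp = np.zeros(n_win)
    n_fly_days = 0
    for s in series_list:
        if s.bin_seconds != series_list[0].bin_seconds:
            raise ValueError("all series must share the bin duration")
        sleep, _ = detect_sleep(s)
        nd = s.n_complete_days
        c = s.counts[: nd * s.bins_per_day].reshape(nd, n_win, per_win)
        z = sleep[: nd * s.bins_per_day].reshape(nd, n_win, per_win)
        act += c.sum(axis=2).sum(axis=0)
        slp += z.sum(axis=2).sum(axis=0) * bin_min
        n_fly_days += nd
    return pd.DataFrame(
        {
            "zt_hours": np.arange(n_win) * window_min / 60.0,
            "activity": act / n_fly_days,
            "sleep_min": slp / n_fly_days,
        }
    )


def exclude_dead(series_list: list[ActivitySeries]) -> list[ActivitySeries]:
    """Drop flies with zero activity over their final 24 h (dead/escaped QC)."""
    kept = []
    for s in series_list:
        tail = s.counts[-s.bins_per_day :]
        if tail.sum() > 0:
            kept.append(s)
    return kept
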
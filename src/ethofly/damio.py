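"""Reading and writing TriKinetics-style DAM monitor files.

A monitor file is tab-delimited with one row per time bin: a reading index,
a date (``dd Mon yy``), a clock time (``HH:MM:SS``), a status code (1 = OK),
six auxiliary columns, and 32 channel count columns (one fly per channel).
The timestamp marks the *end* of the bin it summarizes, so a row stamped
08:00:30 with lights-on at 08:00 covers ZT 0.0000-0.0083 h.

Channels are mapped to flies via a channel map (channel, fly_id, genotype);
unmapped channels are ignored on read and zero-padded on write.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .sleep import ActivitySeries

__all__ = ["DamParseError", "write_dam", "read_dam", "write_channel_map", "read_channel_map"]

N_CHANNELS = 32
N_FIELDS = 10 + N_CHANNELS
_DATE_FMT = "%d %b %y %H:%M:%S"


class DamParseError(ValueError):
    """Malformed DAM monitor file; message carries the 1-based line number."""


@dataclass(frozen=True)
class _Row:
    when: datetime
    status: int
    counts: np.ndarray


def write_dam(
    series_list: list[ActivitySeries],
    path: str | Path,
    start: datetime | None = None,
    lights_on: str = "08:00",
) -> pd.DataFrame:
    """Write up to 32 series as one monitor file; returns the channel map.

    All series must share bin duration and length.  By default the first row
    is stamped one bin after lights-on, i.e. recording starts at ZT0.
    """
    if not series_list:
        raise ValueError("nothing to write")
    if len(series_list) > N_CHANNELS:
        raise ValueError(f"a monitor holds at most {N_CHANNELS} channels")
    bin_s = series_list[0].bin_seconds
    n = series_list[0].counts.size
    for s in series_list:
        if s.bin_seconds != bin_s or s.counts.size != n:
            raise ValueError("all series must share bin duration and length")
    if start is None:
        h, m = (int(x) for x in lights_on.split(":"))
        start = datetime(2024, 1, 1, h, m, 0)
    mat = np.zeros((n, N_CHANNELS), dtype=np.int64)
    for ch, s in enumerate(series_list):
        mat[:, ch] = s.counts
    path = Path(path)
    with path.open("w") as fh:
        for i in range(n):
            when = start + timedelta(seconds=(i + 1) * bin_s)
            fields = [
                str(i + 1),
                when.strftime("%d %b %y"),
                when.strftime("%H:%M:%S"),
                "1",
            ] + ["0"] * 6 + [str(v) for v in mat[i]]
            fh.write("\t".join(fields) + "\n")
    return pd.DataFrame(
        {
            "channel": np.arange(1, len(series_list) + 1),
            "fly_id": [s.fly_id for s in series_list],
            "genotype": [s.genotype for s in series_list],
        }
    )


def _parse_line(line: str, lineno: int) -> _Row:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != N_FIELDS:
        raise DamParseError(
            f"line {lineno}: expected {N_FIELDS} tab-separated fields, got {len(parts)}"
        )
    try:
        when = datetime.strptime(f"{parts[1]} {parts[2]}", _DATE_FMT)
        status = int(parts[3])
        counts = np.array([int(v) for v in parts[10:]], dtype=np.int64)
    except ValueError as exc:
        raise DamParseError(f"line {lineno}: {exc}") from exc
    if (counts < 0).any():
        raise DamParseError(f"line {lineno}: negative count")
    return _Row(when, status, counts)


def read_dam(
    path: str | Path,
    channel_map: pd.DataFrame,
    lights_on: str = "08:00",
) -> list[ActivitySeries]:
    """Parse a monitor file into one :class:`ActivitySeries` per mapped channel.

    Timestamps must be strictly increasing on a constant grid (the bin
    duration is inferred from the first step).  Gaps that are whole multiples
    of the bin are filled with zero counts and flagged in the series'
    ``missing`` mask; rows with a non-1 status are flagged the same way.
    """
    path = Path(path)
    rows: list[_Row] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_line(line, lineno))
    if len(rows) < 2:
        raise DamParseError("monitor file needs at least two rows")
    bin_s = int((rows[1].when - rows[0].when).total_seconds())
    if bin_s <= 0:
        raise DamParseError("line 2: non-monotone timestamp")
    counts: list[np.ndarray] = [rows[0].counts]
    missing: list[bool] = [rows[0].status != 1]
    prev = rows[0].when
    for i, r in enumerate(rows[1:], start=2):
        step = (r.when - prev).total_seconds()
        if step <= 0:
            raise DamParseError(f"line {i}: non-monotone timestamp {r.when}")
        if step % bin_s != 0:
            raise DamParseError(
                f"line {i}: timestamp off the {bin_s}-s grid ({r.when})"
            )
        n_gap = int(step // bin_s) - 1
        for _ in range(n_gap):
            counts.append(np.zeros(N_CHANNELS, dtype=np.int64))
            missing.append(True)
        counts.append(r.counts)
        missing.append(r.status != 1)
        prev = r.when
    mat = np.stack(counts)
    miss = np.array(missing, dtype=bool)

    h, m = (int(x) for x in lights_on.split(":"))
    first_bin_start = rows[0].when - timedelta(seconds=bin_s)
    lights = first_bin_start.replace(hour=h, minute=m, second=0)
    zt_start = ((first_bin_start - lights).total_seconds() / 3600.0) % 24.0

    cmap = channel_map if isinstance(channel_map, pd.DataFrame) else pd.DataFrame(channel_map)
    out = []
    for _, row in cmap.iterrows():
        ch = int(row["channel"])
        if not 1 <= ch <= N_CHANNELS:
            raise ValueError(f"channel {ch} out of range 1..{N_CHANNELS}")
        out.append(
            ActivitySeries(
                fly_id=str(row["fly_id"]),
                genotype=str(row["genotype"]),
                counts=mat[:, ch - 1],
                bin_seconds=bin_s,
                start_zt_hours=zt_start,
                missing=miss.copy() if miss.any() else None,
            )
        )
    return out


def write_channel_map(cmap: pd.DataFrame, path: str | Path) -> None:
    cmap.to_csv(path, index=False)


def read_channel_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"channel", "fly_id", "genotype"}
    if not need.issubset(df.columns):
        raise ValueError(f"channel map needs columns {sorted(need)}")
    return df
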
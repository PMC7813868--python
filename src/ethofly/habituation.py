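"""Light-off jump habituation scoring.

A fly in a light-off jump rig receives a train of light-off pulses (100 by
default) and its startle jumps are recorded per trial, either as a binary
outcome or as a wing-vibration magnitude that is thresholded into one.
Habituation speed is summarized per fly as the trials-to-criterion (TTC):
the 1-based index of the first jump trial that is followed by at least five
consecutive no-jump trials.  Flies that never meet the criterion are
right-censored at the last trial.  A fly is a "jumper" if it jumps at least
once within the first five trials; genotypes are only analyzable when more
than half of their flies are jumpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JumpSeries",
    "TtcResult",
    "GenotypeHabituation",
    "call_jumps",
    "compute_ttc",
    "ttc_matrix",
    "is_jumper",
    "summarize_genotype",
    "filter_genotype",
    "mean_jump_curve",
    "ttc_table",
    "series_to_frame",
    "frame_to_series",
    "read_jump_table",
]

#: number of consecutive no-jump trials that defines the habituation criterion
CRITERION_RUN = 5
#: trials 1..JUMPER_WINDOW define the jumper flag
JUMPER_WINDOW = 5


@dataclass
class JumpSeries:
    """Binary jump outcomes of one fly over a train of light-off trials."""

    fly_id: str
    genotype: str
    jumps: np.ndarray
    replicate: str = "r1"
    magnitude: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.jumps = np.asarray(self.jumps, dtype=np.int8)
        if self.jumps.ndim != 1 or self.jumps.size < CRITERION_RUN:
            raise ValueError(
                f"fly {self.fly_id}: need a 1-D series of >= {CRITERION_RUN} trials"
            )
        if not np.isin(self.jumps, (0, 1)).all():
            raise ValueError(f"fly {self.fly_id}: jumps must be 0/1")
        if self.magnitude is not None:
            self.magnitude = np.asarray(self.magnitude, dtype=float)
            if self.magnitude.shape != self.jumps.shape:
                raise ValueError(
                    f"fly {self.fly_id}: magnitude length must match jumps"
                )

    @property
    def n_trials(self) -> int:
        return int(self.jumps.size)


@dataclass(frozen=True)
class TtcResult:
    """Per-fly trials-to-criterion with censoring and jumper bookkeeping."""

    fly_id: str
    ttc: int
    censored: bool
    jumper: bool


@dataclass
class GenotypeHabituation:
    """Group-level habituation summary for one genotype."""

    genotype: str
    n_total: int
    n_jumpers: int
    ttc: list[int] = field(default_factory=list)  # jumpers only
    mean_jump_response: np.ndarray | None = None

    @property
    def jumper_fraction(self) -> float:
        return self.n_jumpers / self.n_total


def call_jumps(magnitude: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a wing-vibration magnitude trace into binary jumps.

    A trial is called a jump when its magnitude strictly exceeds ``threshold``
    (the rig's noise floor).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    magnitude = np.asarray(magnitude, dtype=float)
    return (magnitude > threshold).astype(np.int8)


def compute_ttc(jumps: np.ndarray, fly_id: str = "") -> TtcResult:
    """Score one jump series as trials-to-criterion.

    TTC is the 1-based index of the first jump trial followed by at least
    ``CRITERION_RUN`` consecutive no-jump trials.  A jump too close to the
    end of the train (fewer than five trials remaining) cannot satisfy the
    criterion.  Flies with jumps but no qualifying trial are censored at the
    last trial, as are flies that never jump (with ``jumper=False``).
    """
    jumps = np.asarray(jumps, dtype=np.int8)
    n = jumps.size
    if n < CRITERION_RUN:
        raise ValueError(f"series must have >= {CRITERION_RUN} trials, got {n}")
    jumper = bool(jumps[:JUMPER_WINDOW].any())
    if not jumps.any():
        return TtcResult(fly_id, n, True, False)
    # candidate jump at 0-based index j needs j+CRITERION_RUN <= n-1
    for j in np.flatnonzero(jumps):
        if j + CRITERION_RUN > n - 1:
            break
        if not jumps[j + 1 : j + 1 + CRITERION_RUN].any():
            return TtcResult(fly_id, int(j) + 1, False, jumper)
    return TtcResult(fly_id, n, True, jumper)


def ttc_matrix(jumps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized TTC over a (flies x trials) 0/1 matrix.

    Returns ``(ttc, censored, jumper)`` arrays; semantics match
    :func:`compute_ttc` row by row.  Used by the simulation-heavy analyses
    where scoring thousands of cohorts one fly at a time would dominate.
    """
    J = np.asarray(jumps, dtype=np.int8)
    if J.ndim != 2 or J.shape[1] < CRITERION_RUN:
        raise ValueError("expected a 2-D matrix with >= 5 trial columns")
    n = J.shape[1]
    jumper = J[:, :JUMPER_WINDOW].any(axis=1)
    # run[:, j] = number of jumps in trials j+1 .. j+5 (0-based), for j <= n-6
    c = np.zeros((J.shape[0], n + 1), dtype=np.int32)
    np.cumsum(J, axis=1, out=c[:, 1:])
    nxt = c[:, CRITERION_RUN + 1 :] - c[:, 1 : n - CRITERION_RUN + 1]
    ok = (J[:, : n - CRITERION_RUN] == 1) & (nxt == 0)
    has = ok.any(axis=1)
    first = np.argmax(ok, axis=1)
    ttc = np.where(has, first + 1, n).astype(np.int64)
    censored = ~has
    return ttc, censored, jumper


def is_jumper(jumps: np.ndarray) -> bool:
    """True iff the fly jumps at least once within trials 1-5."""
    jumps = np.asarray(jumps)
    if jumps.size < JUMPER_WINDOW:
        raise ValueError(f"series must have >= {JUMPER_WINDOW} trials")
    return bool(jumps[:JUMPER_WINDOW].any())


def summarize_genotype(series: list[JumpSeries]) -> GenotypeHabituation:
    """Collect jumper counts, jumper-only TTCs and the mean jump curve."""
    if not series:
        raise ValueError("empty genotype group")
    genotypes = {s.genotype for s in series}
    if len(genotypes) > 1:
        raise ValueError(f"mixed genotypes in one group: {sorted(genotypes)}")
    results = [compute_ttc(s.jumps, s.fly_id) for s in series]
    jumpers = [r for r in results if r.jumper]
    return GenotypeHabituation(
        genotype=series[0].genotype,
        n_total=len(series),
        n_jumpers=len(jumpers),
        ttc=[r.ttc for r in jumpers],
        mean_jump_response=mean_jump_curve(series),
    )


def filter_genotype(group: GenotypeHabituation) -> bool:
    """Inclusion rule: strictly more than 50% of flies must be jumpers."""
    if group.n_total < 1:
        raise ValueError("empty group")
    return group.n_jumpers / group.n_total > 0.5


def mean_jump_curve(series: list[JumpSeries]) -> np.ndarray:
    """Per-trial fraction of flies jumping (denominator: all flies tested)."""
    if not series:
        raise ValueError("empty group")
    lengths = {s.n_trials for s in series}
    if len(lengths) > 1:
        raise ValueError("all series in a group must share the trial count")
    return np.stack([s.jumps for s in series]).mean(axis=0)


def ttc_table(series: list[JumpSeries]) -> pd.DataFrame:
    """Per-fly TTC table (fly_id, genotype, replicate, ttc, censored, jumper)."""
    rows = []
    for s in series:
        r = compute_ttc(s.jumps, s.fly_id)
        rows.append(
            dict(
                fly_id=s.fly_id,
                genotype=s.genotype,
                replicate=s.replicate,
                ttc=r.ttc,
                censored=r.censored,
                jumper=r.jumper,
            )
        )
    return pd.DataFrame(rows)


def series_to_frame(series: list[JumpSeries]) -> pd.DataFrame:
    """Long format: one row per fly x trial, trials numbered from 1."""
    frames = []
    for s in series:
        d = pd.DataFrame(
            {
                "fly_id": s.fly_id,
                "genotype": s.genotype,
                "replicate": s.replicate,
                "trial": np.arange(1, s.n_trials + 1),
                "jump": s.jumps,
            }
        )
        if s.magnitude is not None:
            d["magnitude"] = s.magnitude
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


def frame_to_series(df: pd.DataFrame, threshold: float | None = None) -> list[JumpSeries]:
    """Rebuild per-fly series from a long table.

    If ``threshold`` is given the ``magnitude`` column is thresholded by
    :func:`call_jumps`; otherwise a binary ``jump`` column is required.
    """
    need = {"fly_id", "genotype", "trial"}
    if not need.issubset(df.columns):
        raise ValueError(f"jump table needs columns {sorted(need)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate="r1")
    out: list[JumpSeries] = []
    for (fly, geno, rep), g in df.groupby(["fly_id", "genotype", "replicate"], sort=False):
        g = g.sort_values("trial")
        if threshold is not None:
            if "magnitude" not in g:
                raise ValueError("threshold given but no magnitude column")
            jumps = call_jumps(g["magnitude"].to_numpy(), threshold)
            mag = g["magnitude"].to_numpy()
        else:
            if "jump" not in g:
                raise ValueError("need a jump column (or magnitude + threshold)")
            jumps = g["jump"].to_numpy()
            mag = g["magnitude"].to_numpy() if "magnitude" in g else None
        out.append(JumpSeries(str(fly), str(geno), jumps, str(rep), mag))
    return out


def read_jump_table(path, threshold: float | None = None) -> list[JumpSeries]:
    """Read a long-format CSV of jump (or magnitude) records."""
    return frame_to_series(pd.read_csv(path), threshold=threshold)
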
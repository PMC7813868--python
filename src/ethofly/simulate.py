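"""Synthetic habituation, DAM activity, and qPCR data with known ground truth.

These generators exist so every stage of the analysis can be exercised, and
its estimators validated, without rig recordings: each draws data from the
statistical model the corresponding analysis assumes, and returns the
ground-truth parameters alongside.

Habituation: fly *i* jumps at trial *t* (0-based internally; trial 1 is the
first stimulus in all outputs) with probability ``p0 * exp(-lambda_i * t)``.
The per-fly rate ``lambda_i`` is log-normal around ``lam * genotype_effect``
(median parameterization), so heterogeneity lives in the learning rate while
initial responsiveness ``p0`` separately governs the jumper filter.
``genotype_effect < 1`` slows habituation, mimicking a knockdown with a
habituation deficit.

DAM: each fly is a two-state (active/rest) Markov chain over 30-s bins with
phase-dependent transition probabilities under 12:12 light:dark.  Rest bins
emit zero counts; active bins emit zero-truncated Poisson counts, so a zero
count identifies the rest state exactly.  A genotype's ``sleep_pressure``
multiplies the fall-asleep probability and divides the wake probability.

qPCR: Ct = baseline - log2(expression) + Gaussian technical noise;
reference genes fluctuate around fixed baselines independent of stage and
tissue, as stable references should.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .habituation import JumpSeries
from .sleep import ActivitySeries

__all__ = [
    "HabituationSimParams",
    "DamSimParams",
    "QpcrSimParams",
    "simulate_habituation",
    "simulate_dam",
    "simulate_qpcr",
    "expected_jump_curve",
    "stationary_rest_fraction",
    "write_ground_truth",
]


@dataclass(frozen=True)
class HabituationSimParams:
    n_flies: int = 100
    n_trials: int = 100
    p0: float = 0.9
    lam: float = 0.1  # median per-trial habituation rate
    heterogeneity_sd: float = 0.3  # log-scale sd of per-fly lambda
    genotype_effect: float = 1.0  # multiplier on lambda; < 1 slows habituation
    genotype: str = "control"
    replicate: str = "r1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must lie in (0, 1]")
        if self.lam < 0 or self.heterogeneity_sd < 0:
            raise ValueError("lambda and heterogeneity sd must be >= 0")
        if self.genotype_effect <= 0:
            raise ValueError("genotype effect must be > 0")
        if self.n_trials < 5 or self.n_flies < 1:
            raise ValueError("need n_trials >= 5 and n_flies >= 1")


def simulate_habituation(
    params: HabituationSimParams,
) -> tuple[list[JumpSeries], pd.DataFrame]:
    """Draw per-fly jump series; returns (series, ground-truth table)."""
    rng = np.random.default_rng(params.seed)
    med = params.lam * params.genotype_effect
    lam_i = med * np.exp(params.heterogeneity_sd * rng.standard_normal(params.n_flies))
    t = np.arange(params.n_trials)
    p = params.p0 * np.exp(-np.outer(lam_i, t))
    jumps = (rng.random((params.n_flies, params.n_trials)) < p).astype(np.int8)
    series = [
        JumpSeries(
            fly_id=f"{params.genotype}_{params.replicate}_{i:04d}",
            genotype=params.genotype,
            jumps=jumps[i],
            replicate=params.replicate,
        )
        for i in range(params.n_flies)
    ]
    truth = pd.DataFrame(
        {
            "fly_id": [s.fly_id for s in series],
            "genotype": params.genotype,
            "lambda_i": lam_i,
            "p0": params.p0,
        }
    )
    return series, truth


def expected_jump_curve(params: HabituationSimParams, n_nodes: int = 200) -> np.ndarray:
    """E[p0 * exp(-lambda_i t)] under the log-normal rate, by Gauss-Hermite."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    lam = (
        params.lam
        * params.genotype_effect
        * np.exp(params.heterogeneity_sd * np.sqrt(2.0) * x)
    )
    t = np.arange(params.n_trials)
    curve = params.p0 * np.exp(-np.outer(lam, t))
    return (w / np.sqrt(np.pi)) @ curve


@dataclass(frozen=True)
class DamSimParams:
    n_flies: int = 32
    n_days: int = 4
    bin_seconds: int = 30
    day_hours: float = 12.0  # lights on ZT0 .. ZT day_hours
    p_fall_asleep: dict = field(
        default_factory=lambda: {"day": 0.04, "night": 0.08}
    )  # active -> rest, per bin
    p_wake: dict = field(
        default_factory=lambda: {"day": 0.06, "night": 0.02}
    )  # rest -> active, per bin
    activity_rate: float = 2.0  # Poisson mean of an active bin (zero-truncated)
    sleep_pressure: float = 1.0  # genotype modifier; > 1 promotes rest
    genotype: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.p_fall_asleep, self.p_wake):
            for phase in ("day", "night"):
                if not 0 <= d[phase] <= 1:
                    raise ValueError("transition probabilities must lie in [0, 1]")
        if self.activity_rate <= 0:
            raise ValueError("Poisson activity rate must be > 0")
        if self.sleep_pressure <= 0:
            raise ValueError("sleep pressure must be > 0")
        if 300 % self.bin_seconds != 0:
            raise ValueError("bin duration must divide 300 s")

    def effective_rates(self, phase: str) -> tuple[float, float]:
        """(fall-asleep, wake) per-bin probabilities after the genotype modifier."""
        fall = min(1.0, self.p_fall_asleep[phase] * self.sleep_pressure)
        wake = min(1.0, self.p_wake[phase] / self.sleep_pressure)
        return fall, wake


def stationary_rest_fraction(params: DamSimParams, phase: str) -> float:
    """Stationary P(rest) of the two-state chain in one phase."""
    fall, wake = params.effective_rates(phase)
    if fall + wake == 0:
        return 0.0
    return fall / (fall + wake)


def _truncated_poisson(rng: np.random.Generator, mu: float, size: int) -> np.ndarray:
    """Poisson(mu) conditioned on >= 1, by inverse CDF above P(0)."""
    from scipy import stats as sps

    p0 = np.exp(-mu)
    u = rng.uniform(p0, 1.0, size)
    return sps.poisson.ppf(u, mu).astype(np.int64)


def simulate_dam(params: DamSimParams) -> tuple[list[ActivitySeries], pd.DataFrame]:
    """Simulate DAM recordings; returns (series, ground-truth table).

    The recording starts at ZT0 (lights-on); state 1 = rest.  Initial states
    are drawn from the day-phase stationary distribution.
    """
    rng = np.random.default_rng(params.seed)
    bins_per_day = 86400 // params.bin_seconds
    n_bins = params.n_days * bins_per_day
    day_bins = int(round(params.day_hours * 3600 / params.bin_seconds))
    phase_is_day = (np.arange(n_bins) % bins_per_day) < day_bins
    fall = np.where(phase_is_day, *[params.effective_rates(p)[0] for p in ("day", "night")])
    wake = np.where(phase_is_day, *[params.effective_rates(p)[1] for p in ("day", "night")])
    state = (
        rng.random(params.n_flies) < stationary_rest_fraction(params, "day")
    ).astype(np.int8)
    rest = np.empty((params.n_flies, n_bins), dtype=bool)
    for b in range(n_bins):
        rest[:, b] = state == 1
        u = rng.random(params.n_flies)
        state = np.where(
            state == 1, (u >= wake[b]).astype(np.int8), (u < fall[b]).astype(np.int8)
        )
    counts = np.zeros((params.n_flies, n_bins), dtype=np.int64)
    active = ~rest
    counts[active] = _truncated_poisson(rng, params.activity_rate, int(active.sum()))
    series = [
        ActivitySeries(
            fly_id=f"{params.genotype}_{i:03d}",
            genotype=params.genotype,
            counts=counts[i],
            bin_seconds=params.bin_seconds,
            start_zt_hours=0.0,
        )
        for i in range(params.n_flies)
    ]
    truth = pd.DataFrame(
        {
            "fly_id": [s.fly_id for s in series],
            "genotype": params.genotype,
            "sleep_pressure": params.sleep_pressure,
            "rest_fraction_day": stationary_rest_fraction(params, "day"),
            "rest_fraction_night": stationary_rest_fraction(params, "night"),
        }
    )
    return series, truth


@dataclass(frozen=True)
class QpcrSimParams:
    stages: tuple = ("L3", "PU", "PH", "A0", "A5", "A15", "A30")
    target_gene: str = "target"
    reference_genes: tuple = ("eIF-1A", "alphaTub84B")
    # relative expression of the target in the body per stage (arbitrary units)
    body_expression: tuple = (0.2, 0.2, 0.6, 1.0, 1.0, 0.9, 0.8)
    # brain/body expression ratio per stage (rises after metamorphosis for a
    # brain-enriched transcript)
    brain_enrichment: tuple = (1.0, 1.0, 4.0, 8.0, 8.0, 8.0, 8.0)
    target_baseline_ct: float = 26.0
    reference_baseline_ct: tuple = (18.0, 21.0)
    noise_sd: float = 0.2  # technical noise, Ct units
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.body_expression) != len(self.stages) or len(
            self.brain_enrichment
        ) != len(self.stages):
            raise ValueError("per-stage parameter length must match stages")
        if any(e <= 0 for e in self.body_expression) or any(
            e <= 0 for e in self.brain_enrichment
        ):
            raise ValueError("expression values must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need >= 1 replicate")


def simulate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Tidy Ct table (gene, tissue, stage, replicate, ct) with ground truth noise."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for si, stage in enumerate(params.stages):
        expr = {
            "body": params.body_expression[si],
            "brain": params.body_expression[si] * params.brain_enrichment[si],
        }
        for tissue in ("brain", "body"):
            for rep in range(1, params.n_replicates + 1):
                rows.append(
                    dict(
                        gene=params.target_gene,
                        tissue=tissue,
                        stage=stage,
                        replicate=f"rep{rep}",
                        ct=params.target_baseline_ct
                        - np.log2(expr[tissue])
                        + params.noise_sd * rng.standard_normal(),
                    )
                )
                for ref, base in zip(params.reference_genes, params.reference_baseline_ct):
                    rows.append(
                        dict(
                            gene=ref,
                            tissue=tissue,
                            stage=stage,
                            replicate=f"rep{rep}",
                            ct=base + params.noise_sd * rng.standard_normal(),
                        )
                    )
    return pd.DataFrame(rows)


def write_ground_truth(params, path: str | Path) -> None:
    """JSON sidecar recording the exact generator parameters."""
    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")
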
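"""Inferential machinery: log-TTC GLM and many-to-one Dunnett comparisons.

Two families of contrasts are supported:

* ``ttc_glm`` — habituation contrasts.  Trials-to-criterion is analyzed on
  the natural-log scale with an ordinary linear model (genotype indicator,
  optional replicate fixed effects).  The raw p comes from the genotype
  coefficient's t-test; multiplicity over RNAi lines sharing a control is
  handled by Bonferroni (p_adj = min(1, p * n_rnai)).  The fold change is
  exp(coefficient), i.e. the ratio of geometric-mean TTCs when no
  covariates are present.

* ``anova_dunnett`` — activity/sleep metrics.  One-way ANOVA followed by
  Dunnett's many-to-one post-hoc test of each treatment against the shared
  control.  The family-wise adjusted p is evaluated here from first
  principles: the vector of contrast t statistics is equicorrelated
  multivariate t with correlations ``lambda_i * lambda_j``,
  ``lambda_i = sqrt(n_i / (n_i + n_0))``, so conditioning on the control's
  standardized mean and on the pooled-SD scale factor makes the contrasts
  independent.  P(max_i |T_i| <= q) is then a 2-D integral (Gauss-Hermite
  over the control deviate, Gauss-Legendre over the chi-distributed scale),
  and p_adj = 1 - that probability at |t_observed|.  A Monte Carlo sampler
  of the same max-|t| law is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "ComparisonResult",
    "DunnettContrast",
    "DunnettFamily",
    "ttc_glm",
    "anova_dunnett",
    "dunnett_sf",
    "dunnett_critical",
    "dunnett_max_abs_t_mc",
    "normalize_to_control",
    "significance_stars",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One knockdown-vs-control contrast on one metric."""

    contrast: str
    estimate: float  # difference of means on the analysis scale
    fold_change: float
    p: float
    p_adj: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.p_adj <= 1):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass(frozen=True)
class DunnettContrast:
    contrast: str
    estimate: float
    t: float
    p: float  # unadjusted two-sided t
    p_adj: float  # Dunnett family-wise
    n: int


@dataclass(frozen=True)
class DunnettFamily:
    control: str
    anova_f: float
    anova_p: float
    df_error: int
    pooled_sd: float
    contrasts: list[DunnettContrast]


# ---------------------------------------------------------------------------
# log-TTC general linear model


def ttc_glm(
    case_ttc,
    control_ttc,
    n_rnai: int = 1,
    case_label: str = "knockdown",
    control_label: str = "control",
    case_replicate=None,
    control_replicate=None,
) -> ComparisonResult:
    """Log-TTC linear model contrast of one knockdown against its control."""
    case = np.asarray(case_ttc, dtype=float)
    ctrl = np.asarray(control_ttc, dtype=float)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    if (case < 1).any() or (ctrl < 1).any():
        raise ValueError("TTC values must be >= 1")
    if n_rnai < 1:
        raise ValueError("n_rnai must be >= 1")
    y = np.log(np.concatenate([ctrl, case]))
    g = np.concatenate([np.zeros(ctrl.size), np.ones(case.size)])
    if np.ptp(y) == 0:
        raise ValueError("degenerate model: zero variance in log TTC")
    X = pd.DataFrame({"const": 1.0, "genotype": g})
    if case_replicate is not None or control_replicate is not None:
        if case_replicate is None or control_replicate is None:
            raise ValueError("replicate labels must cover both groups")
        rep = np.concatenate(
            [np.asarray(control_replicate), np.asarray(case_replicate)]
        )
        X = pd.concat(
            [X, pd.get_dummies(pd.Series(rep), prefix="rep", drop_first=True, dtype=float)],
            axis=1,
        )
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params["genotype"])
    p = float(fit.pvalues["genotype"])
    return ComparisonResult(
        contrast=f"{case_label} vs {control_label}",
        estimate=coef,
        fold_change=float(np.exp(coef)),
        p=p,
        p_adj=min(1.0, p * n_rnai),
        n_case=case.size,
        n_control=ctrl.size,
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one post-hoc


def _lambdas(n_treat: np.ndarray, n_control: int) -> np.ndarray:
    return np.sqrt(n_treat / (n_treat + n_control))


def _max_abs_t_cdf(
    q: float, lambdas: np.ndarray, df: int, n_z: int = 96, n_s: int = 128
) -> float:
    """P(max_i |T_i| <= q) for the Dunnett max-|t| statistic."""
    if q <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    c = np.sqrt(1.0 - lam**2)
    # Gauss-Hermite for the shared control deviate z0 ~ N(0, 1)
    xh, wh = np.polynomial.hermite.hermgauss(n_z)
    z0 = np.sqrt(2.0) * xh
    wz = wh / np.sqrt(np.pi)
    # Gauss-Legendre for s = sqrt(chi2_df / df)
    lo = stats.chi.ppf(1e-12, df) / np.sqrt(df)
    hi = stats.chi.ppf(1.0 - 1e-12, df) / np.sqrt(df)
    xl, wl = np.polynomial.legendre.leggauss(n_s)
    s = 0.5 * (hi - lo) * xl + 0.5 * (hi + lo)
    ws = 0.5 * (hi - lo) * wl * stats.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df)
    # inner product over contrasts on the (s, z0) grid
    S = s[:, None, None]
    Z = z0[None, :, None]
    L = lam[None, None, :]
    C = c[None, None, :]
    upper = (q * S - L * Z) / C
    lower = (-q * S - L * Z) / C
    inner = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=2)
    return float(ws @ (inner @ wz))


def dunnett_sf(t: float, n_treat, n_control: int, df: int) -> float:
    """Two-sided Dunnett-adjusted p: P(max_i |T_i| >= |t|)."""
    lam = _lambdas(np.asarray(n_treat, dtype=float), n_control)
    return min(1.0, max(0.0, 1.0 - _max_abs_t_cdf(abs(t), lam, df)))


def dunnett_critical(alpha: float, n_treat, n_control: int, df: int) -> float:
    """Two-sided family-wise critical value: P(max |T| > c) = alpha."""
    lam = _lambdas(np.asarray(n_treat, dtype=float), n_control)
    return float(
        optimize.brentq(
            lambda q: _max_abs_t_cdf(q, lam, df) - (1.0 - alpha), 1e-6, 50.0
        )
    )


def dunnett_max_abs_t_mc(
    n_treat, n_control: int, df: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo draws of the max-|t| null, for cross-checking the quadrature."""
    lam = _lambdas(np.asarray(n_treat, dtype=float), n_control)
    k = lam.size
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    t = (lam[None, :] * z0[:, None] + np.sqrt(1 - lam**2)[None, :] * z) / s[:, None]
    return np.abs(t).max(axis=1)


def anova_dunnett(groups: dict[str, np.ndarray], control: str) -> DunnettFamily:
    """One-way ANOVA with Dunnett's post-hoc against the named control."""
    if control not in groups:
        raise ValueError(f"control group {control!r} not in groups")
    if len(groups) < 2:
        raise ValueError("need a control and at least one treatment group")
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrs.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    ctrl = arrs[control]
    treat = {k: v for k, v in arrs.items() if k != control}
    n_tot = sum(v.size for v in arrs.values())
    k_all = len(arrs)
    df_err = n_tot - k_all
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in arrs.values())
    if ss_err == 0:
        raise ValueError("degenerate: zero within-group variance")
    ms_err = ss_err / df_err
    pooled_sd = float(np.sqrt(ms_err))
    f_stat, f_p = stats.f_oneway(*arrs.values())
    ns = np.array([v.size for v in treat.values()], dtype=float)
    contrasts = []
    for (label, v), n_i in zip(treat.items(), ns):
        est = float(v.mean() - ctrl.mean())
        se = pooled_sd * np.sqrt(1.0 / n_i + 1.0 / ctrl.size)
        t = est / se
        p_raw = 2.0 * stats.t.sf(abs(t), df_err)
        p_adj = dunnett_sf(t, ns, ctrl.size, df_err)
        contrasts.append(
            DunnettContrast(
                contrast=f"{label} vs {control}",
                estimate=est,
                t=float(t),
                p=float(min(1.0, p_raw)),
                p_adj=float(max(p_adj, min(1.0, p_raw))),
                n=int(n_i),
            )
        )
    return DunnettFamily(
        control=control,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        df_error=df_err,
        pooled_sd=pooled_sd,
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------


def normalize_to_control(values, control_mean: float) -> np.ndarray:
    """Express metric values as percent of the control-group mean."""
    if control_mean == 0:
        raise ValueError("control mean is zero; percent-of-control undefined")
    return np.asarray(values, dtype=float) / control_mean * 100.0


def significance_stars(p_adj: float) -> str:
    """Figure-style significance annotation at 0.05 / 0.01 / 0.001."""
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"
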
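"""Replicate stochastic projections under avalanche-mortality scenarios.

A scenario fixes the population-level avalanche mortality rate m and
applies it every year.  Each replicate draws one coefficient vector from
the survival fit's covariance (held fixed for the replicate), rebuilds the
stage survivals and change factors from that draw, starts 100 animals at
the baseline stable stage distribution, and projects the population with
yearly lognormal fecundity multipliers.  The replicate's average annual
growth rate is the geometric mean λ = (N_T / N_0)^(1/T).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .population import (
    VitalRateSchedule,
    adjusted_matrix,
    build_matrix,
    largest_remainder_round,
    sample_parameters,
    stable_stage_distribution,
)
from .stages import Stage
from .survival import ChangeFactorTable, SurvivalModelFit, build_neonate_line

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ThresholdResult",
    "run_scenario",
    "scenario_sweep",
    "find_decline_threshold",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """An avalanche-mortality scenario and its simulation protocol."""

    m: float
    horizon_years: int = 30
    n_reps: int = 1000
    initial_n: int = 100
    seed: int = 0
    fecundity_sd: float = 0.106
    # When True, each replicate additionally draws a coefficient vector from
    # the survival fit's covariance and rebuilds survivals and change factors
    # from it (parameter-uncertainty sensitivity mode).  The default protocol
    # applies point-estimate change factors with environmental (fecundity)
    # stochasticity only, which is what reproduces the published replicate
    # quartile bands; see docs/methods.md.
    sample_coefficients: bool = False
    round_initial: bool = True  # largest-remainder integer start vector

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must be in [0, 1]")
        if self.horizon_years < 1 or self.n_reps < 1 or self.initial_n < 1:
            raise ValueError("horizon, n_reps and initial_n must be >= 1")


@dataclass
class ScenarioResult:
    """Per-replicate growth rates and their summary."""

    spec: ScenarioSpec
    lambdas: np.ndarray          # per-replicate average annual λ
    pct_change: np.ndarray       # per-replicate total % change over horizon
    n_extinct: int = 0

    @property
    def mean_lambda(self) -> float:
        return float(np.mean(self.lambdas))

    @property
    def p25(self) -> float:
        return float(np.percentile(self.lambdas, 25))

    @property
    def p75(self) -> float:
        return float(np.percentile(self.lambdas, 75))

    @property
    def decline_fraction(self) -> float:
        """Fraction of replicates ending below the initial population size."""
        return float(np.mean(self.pct_change < 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.lambdas)),
                "lambda": self.lambdas,
                "pct_change": self.pct_change,
            }
        )


def run_scenario(
    spec: ScenarioSpec,
    fit: SurvivalModelFit,
    schedule: VitalRateSchedule,
    s_neo: float | None = None,
) -> ScenarioResult:
    """Simulate one avalanche-mortality scenario.

    The schedule must be calibrated at the same mean rate the change
    factors are anchored to (``schedule.m_mean``).  Deterministic for a
    fixed ``spec.seed``.
    """
    m_mean = schedule.m_mean
    s_neo = schedule.s_neo if s_neo is None else s_neo
    baseline = build_matrix(schedule)
    ssd = stable_stage_distribution(baseline)
    if spec.round_initial:
        start = largest_remainder_round(ssd, spec.initial_n).astype(float)
    else:
        start = ssd * spec.initial_n

    rng = np.random.default_rng(spec.seed)
    lambdas = np.empty(spec.n_reps)
    pct = np.empty(spec.n_reps)
    n_extinct = 0
    T = spec.horizon_years

    def scenario_matrices(rep_fit: SurvivalModelFit):
        # survivals at m_mean from the (possibly drawn) coefficients, then
        # the change factors that carry them to the scenario rate m
        matrix = build_matrix(_reschedule(schedule, rep_fit))
        table = ChangeFactorTable(
            fit=rep_fit,
            neonate_line=build_neonate_line(rep_fit, s_neo, m_mean),
            m_mean=m_mean,
        )
        A = adjusted_matrix(matrix, table.factors_at(spec.m))
        fert = A * matrix.fertility_mask
        return A - fert, fert

    if not spec.sample_coefficients:
        surv, fert = scenario_matrices(fit)

    for r in range(spec.n_reps):
        draw = sample_parameters(fit, spec.fecundity_sd, horizon=T, seed=rng)
        if spec.sample_coefficients:
            surv, fert = scenario_matrices(draw.fit)

        state = start.copy()
        mults = draw.fecundity_multipliers
        for t in range(T):
            state = surv @ state + mults[t] * (fert @ state)
        n_end = state.sum()
        n0 = start.sum()
        if n_end <= 0:
            n_extinct += 1
            lambdas[r] = 0.0
            pct[r] = -100.0
        else:
            lambdas[r] = (n_end / n0) ** (1.0 / T)
            pct[r] = (n_end - n0) / n0 * 100.0
    if n_extinct:
        logger.warning("%d of %d replicates went extinct", n_extinct, spec.n_reps)
    return ScenarioResult(spec=spec, lambdas=lambdas, pct_change=pct, n_extinct=n_extinct)


def _reschedule(schedule: VitalRateSchedule, fit: SurvivalModelFit) -> VitalRateSchedule:
    """Schedule with survivals recomputed from ``fit`` at the same m_mean,
    keeping the calibrated fecundity."""
    from .population import schedule_from_fit

    fresh = schedule_from_fit(
        fit,
        fecundity=schedule.fecundity,
        s_neo=schedule.s_neo,
        m_mean=schedule.m_mean,
        birth_sex_ratio=schedule.birth_sex_ratio,
        stage_map=schedule.stage_map,
    )
    return fresh


def scenario_sweep(
    m_values,
    spec_template: ScenarioSpec,
    fit: SurvivalModelFit,
    schedule: VitalRateSchedule,
) -> pd.DataFrame:
    """One summary row per avalanche rate: mean λ and the quartile band.

    The returned frame carries the best-to-worst spread of mean λ in
    percentage points as ``df.attrs["spread_points"]``.
    """
    rows = []
    for i, m in enumerate(m_values):
        if not 0.0 <= m <= 1.0:
            raise ValueError(f"m={m} outside [0, 1]")
        spec = replace(spec_template, m=float(m), seed=spec_template.seed + i)
        res = run_scenario(spec, fit, schedule)
        rows.append(
            {
                "m": float(m),
                "mean_lambda": res.mean_lambda,
                "p25": res.p25,
                "p75": res.p75,
                "decline_fraction": res.decline_fraction,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["spread_points"] = float(
        (df["mean_lambda"].max() - df["mean_lambda"].min()) * 100.0
    )
    return df


@dataclass(frozen=True)
class ThresholdResult:
    """Decline-probability threshold and its Monte-Carlo uncertainty."""

    m_star: float
    decline_prob: float
    wilson_ci: tuple[float, float]
    n_reps: int
    boundary: str | None = None  # set when the target sits outside the bracket


def _wilson(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (center - half, center + half)


def find_decline_threshold(
    fit: SurvivalModelFit,
    schedule: VitalRateSchedule,
    horizon: int = 30,
    decline_prob_target: float = 0.5,
    tolerance: float = 0.002,
    n_reps: int = 1000,
    bracket: tuple[float, float] = (0.04, 0.15),
    seed: int = 0,
    spec_template: ScenarioSpec | None = None,
) -> ThresholdResult:
    """Bisection on m for P(population declines over ``horizon``) = target.

    Uses common random numbers (the same replicate seed at every trial m)
    so the estimated P(decline) is monotone in m and bisection is stable;
    ``tolerance`` is the half-width of the final bracket on m.
    """

    def prob(m: float) -> float:
        spec = ScenarioSpec(
            m=m,
            horizon_years=horizon,
            n_reps=n_reps,
            initial_n=spec_template.initial_n if spec_template else 100,
            seed=seed,
            fecundity_sd=spec_template.fecundity_sd if spec_template else 0.106,
            sample_coefficients=(
                spec_template.sample_coefficients if spec_template else False
            ),
        )
        return run_scenario(spec, fit, schedule).decline_fraction

    lo, hi = bracket
    p_lo, p_hi = prob(lo), prob(hi)
    if p_lo >= decline_prob_target:
        if decline_prob_target <= 0.0:
            return ThresholdResult(lo, p_lo, _wilson(p_lo, n_reps), n_reps, "lower")
        raise ValueError(
            f"bracket does not straddle the target: P({lo})={p_lo:.3f} >= {decline_prob_target}"
        )
    if p_hi <= decline_prob_target:
        raise ValueError(
            f"bracket does not straddle the target: P({hi})={p_hi:.3f} <= {decline_prob_target}"
        )
    while hi - lo > 2 * tolerance:
        mid = 0.5 * (lo + hi)
        if prob(mid) < decline_prob_target:
            lo = mid
        else:
            hi = mid
    m_star = 0.5 * (lo + hi)
    p_star = prob(m_star)
    return ThresholdResult(m_star, p_star, _wilson(p_star, n_reps), n_reps)
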
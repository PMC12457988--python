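"""Recovery times after a decline, and empirical event recurrence.

A population reduced by a fraction d and growing at rate λ > 1 regains its
original size after

    t = log(1 / (1 − d)) / log(λ)   years,

the closed form used throughout; quartile growth rates give a recovery-time
band.  Event frequency is summarized empirically: the exceedance
probability of a magnitude is the fraction of observed years meeting or
exceeding it, and its reciprocal is the recurrence interval (average
waiting time in years).  Three generation-anchored scenarios tie the two
together: the largest observed event, the largest event expected within
one generation, and the event whose recovery takes one generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import optimize

from .population import VitalRateSchedule
from .scenarios import ScenarioSpec, run_scenario
from .survival import SurvivalModelFit
from .synthetic import EventSeries

__all__ = [
    "RecoveryEstimate",
    "RecurrenceEstimate",
    "AnchoredScenario",
    "recovery_time",
    "recovery_band",
    "exceedance",
    "generation_anchored_scenarios",
]


def recovery_time(decline: float, lambda_rec: float) -> float:
    """Years for a population down by ``decline`` to regain its size at
    growth rate ``lambda_rec``."""
    if not 0.0 <= decline < 1.0:
        raise ValueError(f"decline must be in [0, 1), got {decline}")
    if lambda_rec <= 1.0:
        raise ValueError(
            "population cannot recover at non-positive growth (lambda <= 1)"
        )
    if decline == 0.0:
        return 0.0
    return math.log(1.0 / (1.0 - decline)) / math.log(lambda_rec)


@dataclass(frozen=True)
class RecoveryEstimate:
    """Point recovery time with its quartile-growth band (years)."""

    decline: float
    lambda_rec: float
    years: float
    years_at_p25: float  # slower growth -> longer recovery
    years_at_p75: float

    def __post_init__(self) -> None:
        assert self.years_at_p75 <= self.years <= self.years_at_p25


def recovery_band(
    decline: float, lambda_mean: float, lambda_p25: float, lambda_p75: float
) -> RecoveryEstimate:
    """Recovery time at the mean and quartile growth rates."""
    if not (1.0 < lambda_p25 <= lambda_mean <= lambda_p75):
        raise ValueError("need 1 < lambda_p25 <= lambda_mean <= lambda_p75")
    return RecoveryEstimate(
        decline=decline,
        lambda_rec=lambda_mean,
        years=recovery_time(decline, lambda_mean),
        years_at_p25=recovery_time(decline, lambda_p25),
        years_at_p75=recovery_time(decline, lambda_p75),
    )


@dataclass(frozen=True)
class RecurrenceEstimate:
    """Empirical exceedance probability and recurrence interval."""

    threshold: float
    exceedance_p: float
    recurrence_years: float
    n: int
    extrapolated: bool = False


def exceedance(series: EventSeries, threshold: float) -> RecurrenceEstimate:
    """Fraction of years with magnitude >= threshold, and its reciprocal.

    A threshold above the observed maximum is reported at the resolution
    of the record (probability 1/n) with the ``extrapolated`` flag set.
    """
    if series.n < 1:
        raise ValueError("empty event series")
    k = sum(1 for v in series.values if v >= threshold)
    if k == 0:
        return RecurrenceEstimate(
            threshold=threshold,
            exceedance_p=1.0 / series.n,
            recurrence_years=float(series.n),
            n=series.n,
            extrapolated=True,
        )
    return RecurrenceEstimate(
        threshold=threshold,
        exceedance_p=k / series.n,
        recurrence_years=series.n / k,
        n=series.n,
    )


@dataclass(frozen=True)
class AnchoredScenario:
    """One generation-anchored avalanche scenario, fully summarized."""

    label: str
    m: float
    decline: float
    recovery_years: float
    recurrence_years: float
    annual_chance: float
    out_of_range: bool = False


def _decline_at(
    m: float,
    fit: SurvivalModelFit,
    schedule: VitalRateSchedule,
    spec: ScenarioSpec,
) -> float:
    """Proportional one-winter loss: 1 − mean annual λ of a 2-year run."""
    res = run_scenario(replace(spec, m=float(m), horizon_years=2), fit, schedule)
    return 1.0 - res.mean_lambda


def generation_anchored_scenarios(
    series: EventSeries,
    generation_time: float,
    fit: SurvivalModelFit,
    schedule: VitalRateSchedule,
    lambda_rec: float = 1.015,
    spec: ScenarioSpec | None = None,
) -> list[AnchoredScenario]:
    """The three headline scenarios.

    1. *Worst case*: the maximum observed event.
    2. *Once in a generation*: the k-th largest event with
       k = round(n / generation_time) — the magnitude exceeded on average
       once per generation.
    3. *Generational recovery*: the event whose decline takes exactly one
       generation to recover at ``lambda_rec``; solved on the deterministic
       2-year decline curve, flagged out-of-range if no observed magnitude
       produces that deep a decline.

    Declines come from 2-year (single-winter) scenario runs; recovery times
    from the closed form at ``lambda_rec``.
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    if spec is None:
        spec = ScenarioSpec(m=0.0, n_reps=400, seed=7)

    def summarize(label: str, m: float, out_of_range: bool = False) -> AnchoredScenario:
        d = max(0.0, _decline_at(m, fit, schedule, spec))
        rec = exceedance(series, m)
        return AnchoredScenario(
            label=label,
            m=float(m),
            decline=d,
            recovery_years=recovery_time(d, lambda_rec),
            recurrence_years=rec.recurrence_years,
            annual_chance=rec.exceedance_p,
            out_of_range=out_of_range,
        )

    m_max = max(series.values)
    out = [summarize("worst_case", m_max)]

    k = max(1, min(series.n, round(series.n / generation_time)))
    m_gen = sorted(series.values, reverse=True)[k - 1]
    out.append(summarize("once_in_a_generation", m_gen))

    target_decline = 1.0 - lambda_rec ** (-generation_time)
    det = replace(spec, n_reps=1, sample_coefficients=False, fecundity_sd=0.0)

    def gap(m: float) -> float:
        return _decline_at(m, fit, schedule, det) - target_decline

    if gap(m_max) < 0:
        out.append(
            AnchoredScenario(
                label="generational_recovery",
                m=m_max,
                decline=target_decline,
                recovery_years=generation_time,
                recurrence_years=exceedance(series, m_max).recurrence_years,
                annual_chance=exceedance(series, m_max).exceedance_p,
                out_of_range=True,
            )
        )
    else:
        m3 = optimize.brentq(gap, 0.0, m_max, xtol=1e-5)
        out.append(summarize("generational_recovery", m3))
    return out
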
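"""Survival versus population-level avalanche mortality.

The core statistical object is a binomial mixed model on the logit scale:

    logit S(stage, m) = β0 + offset(stage) + β_avy · m + u_individual

where m is the proportion of the whole population killed by avalanches in a
year (a *population-level* covariate, entered as a proportion, e.g. 0.07)
and u_individual ~ N(0, σ²) is an individual random intercept.  Old males
are the reference category.

From a fit this module derives:

* predicted stage survival at any avalanche mortality rate m
  (at the median individual, u = 0);
* the *proportional survival change factor*
  Ŝ_change(stage, m) = S(stage, m) / S(stage, m_mean), the ratio used to
  rescale baseline vital rates under avalanche scenarios — 1 at the mean
  rate, < 1 above it, > 1 below it (for a negative slope);
* a neonate logit line sharing the fitted slope, anchored so that survival
  at m_mean equals a configured first-year survival S_neo (neonates are not
  radio-marked, so their intercept cannot be estimated from known fates);
* a population-weighted survival curve over a grid of m, for comparison
  with the fully-additive expectation S(m) = S(0) − m.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .glmm import FittingError, fit_binomial_random_intercept
from .stages import MODELED_STAGES, OFFSET_STAGES, REFERENCE_STAGE, Stage

__all__ = [
    "SurvivalModelFit",
    "NeonateLine",
    "ChangeFactorTable",
    "reference_fit",
    "fit_survival_model",
    "predict_survival",
    "change_factor",
    "build_neonate_line",
    "additivity_curve",
]

logger = logging.getLogger(__name__)

#: fixed-effect coefficient order used everywhere
COEF_NAMES: tuple[str, ...] = ("intercept", "avalanche_mortality") + tuple(
    s.value for s in OFFSET_STAGES
)


@dataclass
class SurvivalModelFit:
    """Logit-scale fixed effects of the survival model, with uncertainty.

    ``stage_offsets`` holds the six non-reference stage offsets (reference:
    old male).  ``coefficient_covariance`` is 8×8 in :data:`COEF_NAMES`
    order.
    """

    intercept: float
    slope: float
    stage_offsets: Mapping[Stage, float]
    coefficient_covariance: np.ndarray
    random_intercept_sd: float = 0.0
    n_animal_years: int = 0

    def __post_init__(self) -> None:
        self.stage_offsets = {Stage(k): float(v) for k, v in self.stage_offsets.items()}
        missing = set(OFFSET_STAGES) - set(self.stage_offsets)
        if missing:
            raise ValueError(f"missing stage offsets: {sorted(s.value for s in missing)}")
        cov = np.asarray(self.coefficient_covariance, float)
        if cov.shape != (8, 8):
            raise ValueError(f"coefficient covariance must be 8x8, got {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("coefficient covariance must be symmetric")
        self.coefficient_covariance = cov

    @property
    def beta(self) -> np.ndarray:
        """Coefficient vector in :data:`COEF_NAMES` order."""
        return np.array(
            [self.intercept, self.slope]
            + [self.stage_offsets[s] for s in OFFSET_STAGES]
        )

    def offset(self, stage: Stage) -> float:
        stage = Stage(stage)
        if stage is REFERENCE_STAGE:
            return 0.0
        if stage not in self.stage_offsets:
            raise KeyError(f"no offset for stage {stage.value!r}")
        return self.stage_offsets[stage]

    def linear_predictor(self, stage: Stage, m: float) -> float:
        return self.intercept + self.offset(stage) + self.slope * float(m)

    def with_beta(self, beta: np.ndarray) -> "SurvivalModelFit":
        """Copy of this fit with the coefficient vector replaced."""
        beta = np.asarray(beta, float)
        return SurvivalModelFit(
            intercept=float(beta[0]),
            slope=float(beta[1]),
            stage_offsets=dict(zip(OFFSET_STAGES, beta[2:])),
            coefficient_covariance=self.coefficient_covariance,
            random_intercept_sd=self.random_intercept_sd,
            n_animal_years=self.n_animal_years,
        )

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "coef_names": list(COEF_NAMES),
            "beta": self.beta.tolist(),
            "coefficient_covariance": self.coefficient_covariance.tolist(),
            "se": np.sqrt(np.diag(self.coefficient_covariance)).tolist(),
            "random_intercept_sd": self.random_intercept_sd,
            "n_animal_years": self.n_animal_years,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurvivalModelFit":
        payload = json.loads(Path(path).read_text())
        beta = np.asarray(payload["beta"], float)
        return cls(
            intercept=beta[0],
            slope=beta[1],
            stage_offsets=dict(zip(OFFSET_STAGES, beta[2:])),
            coefficient_covariance=np.asarray(payload["coefficient_covariance"], float),
            random_intercept_sd=float(payload["random_intercept_sd"]),
            n_animal_years=int(payload["n_animal_years"]),
        )

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, Wald 95% CI)."""
        se = np.sqrt(np.diag(self.coefficient_covariance))
        beta = self.beta
        return pd.DataFrame(
            {
                "parameter": COEF_NAMES,
                "estimate": beta,
                "se": se,
                "ci_lower": beta - 1.96 * se,
                "ci_upper": beta + 1.96 * se,
            }
        )


# published point estimates and standard errors from the long-term coastal
# Alaska known-fate monitoring program (logit scale; reference: old males)
_REFERENCE_BETA = {
    "intercept": (0.845, 0.186),
    "avalanche_mortality": (-5.475, 1.211),
    Stage.YEARLING: (1.347, 0.780),
    Stage.SUBADULT: (2.627, 0.450),
    Stage.YOUNG_ADULT: (1.742, 0.254),
    Stage.ADULT_FEMALE: (1.549, 0.253),
    Stage.ADULT_MALE: (1.048, 0.218),
    Stage.OLD_FEMALE: (0.741, 0.230),
}


def reference_fit() -> SurvivalModelFit:
    """Survival-model fit built from the published coefficient table.

    Point estimates and SEs come from the coastal Alaska mountain goat
    analysis (421 individuals, 1218 animal-years).  The source prints SEs
    but not the coefficient covariance, so the covariance here is diagonal;
    fits produced by :func:`fit_survival_model` carry the full matrix.
    """
    ses = np.array([v[1] for v in _REFERENCE_BETA.values()])
    return SurvivalModelFit(
        intercept=_REFERENCE_BETA["intercept"][0],
        slope=_REFERENCE_BETA["avalanche_mortality"][0],
        stage_offsets={s: _REFERENCE_BETA[s][0] for s in OFFSET_STAGES},
        coefficient_covariance=np.diag(ses**2),
        random_intercept_sd=0.0,
        n_animal_years=1218,
    )


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "stage": [Stage(r.stage).value for r in records],
            "avalanche_rate": [r.avalanche_rate_that_year for r in records],
            "fate": [getattr(r.fate, "value", r.fate) for r in records],
        }
    )


def fit_survival_model(records) -> SurvivalModelFit:
    """Fit the binomial random-intercept model to known-fate records.

    ``records`` is a sequence of ``KnownFateRecord`` or an equivalent
    DataFrame with columns individual_id, stage, avalanche_rate, fate.
    Outcome coding: survived = 1, any death = 0.  The covariate is the
    population-level avalanche mortality rate of the record's year.

    Raises
    ------
    ValueError
        fewer than 50 animal-years.
    glmm.FittingError
        separation or non-convergence (diagnostics in the message).
    """
    df = _records_to_frame(records)
    if len(df) < 50:
        raise ValueError(f"need >= 50 animal-years, got {len(df)}")
    y = (df["fate"].astype(str) == "survived").to_numpy(float)

    stages_present = [s for s in OFFSET_STAGES if (df["stage"] == s.value).any()]
    if len(stages_present) + int((df["stage"] == REFERENCE_STAGE.value).any()) < 2:
        logger.warning("single life stage present; fitting reduced model without offsets")
        stages_present = []

    X = np.column_stack(
        [np.ones(len(df)), df["avalanche_rate"].to_numpy(float)]
        + [(df["stage"] == s.value).to_numpy(float) for s in stages_present]
    )
    res = fit_binomial_random_intercept(y, X, df["individual_id"].to_numpy())
    if not res.converged:
        raise FittingError("GLMM optimizer reported non-convergence")

    offsets = dict.fromkeys(OFFSET_STAGES, 0.0)
    cov = np.zeros((8, 8))
    idx = [0, 1] + [2 + OFFSET_STAGES.index(s) for s in stages_present]
    for a, ia in enumerate(idx):
        for b, ib in enumerate(idx):
            cov[ia, ib] = res.cov_beta[a, b]
    for k, s in enumerate(stages_present):
        offsets[s] = float(res.beta[2 + k])

    return SurvivalModelFit(
        intercept=float(res.beta[0]),
        slope=float(res.beta[1]),
        stage_offsets=offsets,
        coefficient_covariance=cov,
        random_intercept_sd=res.sigma,
        n_animal_years=len(df),
    )


def predict_survival(fit: SurvivalModelFit, stage: Stage, m: float) -> float:
    """Annual survival of a stage at avalanche mortality rate ``m``.

    Evaluated for the median individual (random intercept 0).  Neonates are
    outside the fitted model; use :func:`build_neonate_line`.
    """
    stage = Stage(stage)
    if stage is Stage.NEONATE:
        raise KeyError("neonate survival comes from the neonate line, not the GLMM fit")
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m must be in [0, 1], got {m}")
    return float(expit(fit.linear_predictor(stage, m)))


def change_factor(fit: SurvivalModelFit, stage: Stage, m: float, m_mean: float) -> float:
    """Proportional survival change factor S(stage, m) / S(stage, m_mean)."""
    denom = predict_survival(fit, stage, m_mean)
    if denom == 0.0:
        raise ZeroDivisionError("survival at the mean avalanche mortality rate is 0")
    return predict_survival(fit, stage, m) / denom


@dataclass(frozen=True)
class NeonateLine:
    """Logit line for first-year survival, sharing the fitted slope.

    The intercept is solved so that survival at the mean avalanche
    mortality rate equals the configured baseline ``s_neo``.
    """

    intercept: float
    slope: float
    s_neo: float
    m_mean: float

    def predict(self, m: float) -> float:
        return float(expit(self.intercept + self.slope * float(m)))

    def change_factor(self, m: float) -> float:
        return self.predict(m) / self.s_neo


def build_neonate_line(fit: SurvivalModelFit, s_neo: float, m_mean: float) -> NeonateLine:
    """Anchor the neonate logit line: intercept = logit(s_neo) − slope·m_mean."""
    if not 0.0 < s_neo < 1.0:
        raise ValueError(f"s_neo must be in (0, 1), got {s_neo}")
    return NeonateLine(
        intercept=float(logit(s_neo) - fit.slope * m_mean),
        slope=fit.slope,
        s_neo=float(s_neo),
        m_mean=float(m_mean),
    )


@dataclass(frozen=True)
class ChangeFactorTable:
    """Per-stage change factors anchored at ``m_mean``.

    Bundles the fitted stage lines and the neonate line so a scenario can
    look up the factor for every stage (neonate included) at any m.
    """

    fit: SurvivalModelFit
    neonate_line: NeonateLine
    m_mean: float

    def at(self, stage: Stage, m: float) -> float:
        stage = Stage(stage)
        if stage is Stage.NEONATE:
            return self.neonate_line.change_factor(m)
        return change_factor(self.fit, stage, m, self.m_mean)

    def factors_at(self, m: float) -> dict[Stage, float]:
        """Factor for every stage (including neonate) at scenario rate m."""
        out = {s: change_factor(self.fit, s, m, self.m_mean) for s in MODELED_STAGES}
        out[Stage.NEONATE] = self.neonate_line.change_factor(m)
        return out


def additivity_curve(
    fit: SurvivalModelFit,
    stage_weights: Mapping[Stage, float],
    m_grid: Sequence[float],
) -> pd.DataFrame:
    """Population-weighted annual survival over a grid of avalanche rates.

    Returns columns ``m``, ``survival`` (stage-weighted mean of the fitted
    lines) and ``fully_additive`` (S(0) − m), the line expected if every
    avalanche death were additional to baseline mortality.
    """
    m_grid = list(m_grid)
    if not m_grid:
        raise ValueError("m_grid is empty")
    weights = {Stage(s): float(w) for s, w in stage_weights.items()}
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stage weights must sum to 1, got {total}")
    surv = [
        sum(w * predict_survival(fit, s, m) for s, w in weights.items())
        for m in m_grid
    ]
    s0 = sum(w * predict_survival(fit, s, 0.0) for s, w in weights.items())
    return pd.DataFrame(
        {"m": m_grid, "survival": surv, "fully_additive": [s0 - m for m in m_grid]}
    )
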
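"""Two-sex, 20-age-class matrix projection model.

The state vector stacks female ages 0–19 then male ages 0–19 (40 entries),
censused once per year just after recruitment.  Recruitment entries fold
the offspring's entire first year of life into the fertility terms:

    F[(sex, 0), (female, a)] = fecundity(a) · S_neo · sex_share

so class 0 holds recruits that have already survived their neonate year,
and the age-0 → age-1 sub-diagonal uses the yearling survival line (first-
year survival is never counted twice).  Survival is constant within a life
stage; the terminal age class does not survive further.

Scenario machinery: per-stage proportional survival change factors rescale
the survival sub-diagonals, the neonate factor and a yearly lognormal
multiplier rescale the fertility rows, and parameter uncertainty enters by
drawing coefficient vectors from the survival fit's covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .stages import DEFAULT_STAGE_MAP, N_AGE_CLASSES, Sex, Stage, StageMap
from .survival import NeonateLine, SurvivalModelFit, predict_survival

__all__ = [
    "VitalRateSchedule",
    "ProjectionMatrix",
    "DrawnParameters",
    "DEFAULT_FECUNDITY_SHAPE",
    "schedule_from_fit",
    "build_matrix",
    "dominant_lambda",
    "stable_stage_distribution",
    "sample_parameters",
    "calibrate_baseline",
    "adjusted_matrix",
    "project_one_year",
    "largest_remainder_round",
]

#: relative age-specific fecundity (kids per female per year, unit plateau):
#: first reproduction at 4, prime output ages 6–9, senescent decline after 10
DEFAULT_FECUNDITY_SHAPE: tuple[float, ...] = (
    0.0, 0.0, 0.0, 0.0,          # ages 0-3: pre-reproductive
    0.3, 0.6,                    # ages 4-5: ramp to maturity
    1.0, 1.0, 1.0, 1.0,          # ages 6-9: plateau
    0.8, 0.8, 0.8, 0.8,          # ages 10-13
    0.5, 0.5, 0.5, 0.5, 0.5, 0.5,  # ages 14-19: senescent
)


@dataclass
class VitalRateSchedule:
    """Per-sex, per-age survival (at m_mean) and female fecundity.

    ``survival_female``/``survival_male`` are length-20 arrays of annual
    survival for the age→age+1 transition; entry 19 is ignored (terminal
    truncation).  ``fecundity`` is kids per female per year by female age.
    ``s_neo`` is first-year offspring survival, which enters only the
    recruitment terms.
    """

    survival_female: np.ndarray
    survival_male: np.ndarray
    fecundity: np.ndarray
    s_neo: float
    birth_sex_ratio: float = 0.5  # proportion female at birth
    m_mean: float = 0.07
    stage_map: StageMap = field(default_factory=lambda: DEFAULT_STAGE_MAP)

    def __post_init__(self) -> None:
        for name in ("survival_female", "survival_male", "fecundity"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (N_AGE_CLASSES,):
                raise ValueError(f"{name} must have length {N_AGE_CLASSES}")
            setattr(self, name, arr)
        if np.any(self.survival_female < 0) or np.any(self.survival_female > 1):
            raise ValueError("female survival outside [0, 1]")
        if np.any(self.survival_male < 0) or np.any(self.survival_male > 1):
            raise ValueError("male survival outside [0, 1]")
        if np.any(self.fecundity < 0):
            raise ValueError("fecundity must be >= 0")
        if not 0.0 <= self.s_neo <= 1.0:
            raise ValueError("s_neo must be in [0, 1]")
        if not 0.0 <= self.birth_sex_ratio <= 1.0:
            raise ValueError("birth_sex_ratio must be in [0, 1]")

    def survival(self, sex: Sex, age: int) -> float:
        arr = self.survival_female if Sex(sex) is Sex.FEMALE else self.survival_male
        return float(arr[age])

    def with_fecundity_scale(self, scale: float) -> "VitalRateSchedule":
        return VitalRateSchedule(
            survival_female=self.survival_female.copy(),
            survival_male=self.survival_male.copy(),
            fecundity=self.fecundity * scale,
            s_neo=self.s_neo,
            birth_sex_ratio=self.birth_sex_ratio,
            m_mean=self.m_mean,
            stage_map=self.stage_map,
        )


def _stage_survivals(fit: SurvivalModelFit, m: float) -> dict[Stage, float]:
    from .stages import MODELED_STAGES

    return {s: predict_survival(fit, s, m) for s in MODELED_STAGES}


def schedule_from_fit(
    fit: SurvivalModelFit,
    fecundity: Sequence[float] = DEFAULT_FECUNDITY_SHAPE,
    s_neo: float = 0.65,
    m_mean: float = 0.07,
    birth_sex_ratio: float = 0.5,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> VitalRateSchedule:
    """Vital-rate schedule with stage survivals evaluated at ``m_mean``."""
    sf = np.empty(N_AGE_CLASSES)
    sm = np.empty(N_AGE_CLASSES)
    for a in range(N_AGE_CLASSES):
        sf[a] = predict_survival(fit, stage_map.projection_stage_of(Sex.FEMALE, a), m_mean)
        sm[a] = predict_survival(fit, stage_map.projection_stage_of(Sex.MALE, a), m_mean)
    sf[-1] = sm[-1] = 0.0  # terminal truncation
    return VitalRateSchedule(
        survival_female=sf,
        survival_male=sm,
        fecundity=np.asarray(fecundity, float),
        s_neo=s_neo,
        birth_sex_ratio=birth_sex_ratio,
        m_mean=m_mean,
        stage_map=stage_map,
    )


@dataclass
class ProjectionMatrix:
    """40×40 projection matrix plus the bookkeeping scenarios need.

    ``survival_mask`` flags the sub-diagonal survival entries and
    ``fertility_mask`` the recruitment entries; ``entry_stage`` labels each
    survival entry with the life stage whose change factor rescales it.
    """

    A: np.ndarray
    schedule: VitalRateSchedule
    survival_mask: np.ndarray
    fertility_mask: np.ndarray
    entry_stage: dict[tuple[int, int], Stage]

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape


def build_matrix(schedule: VitalRateSchedule) -> ProjectionMatrix:
    """Assemble the two-sex projection matrix from a vital-rate schedule."""
    n = N_AGE_CLASSES
    A = np.zeros((2 * n, 2 * n))
    survival_mask = np.zeros_like(A, bool)
    fertility_mask = np.zeros_like(A, bool)
    entry_stage: dict[tuple[int, int], Stage] = {}

    rho = schedule.birth_sex_ratio
    for a in range(n):
        f = schedule.fecundity[a] * schedule.s_neo
        if f > 0:
            A[0, a] = f * rho          # daughters recruited to female class 0
            A[n, a] = f * (1.0 - rho)  # sons recruited to male class 0
            fertility_mask[0, a] = fertility_mask[n, a] = True
    for block, sex in ((0, Sex.FEMALE), (n, Sex.MALE)):
        for a in range(n - 1):
            i, j = block + a + 1, block + a
            A[i, j] = schedule.survival(sex, a)
            survival_mask[i, j] = True
            entry_stage[(i, j)] = schedule.stage_map.projection_stage_of(sex, a)
    return ProjectionMatrix(A, schedule, survival_mask, fertility_mask, entry_stage)


def dominant_lambda(matrix: ProjectionMatrix | np.ndarray) -> float:
    """Dominant eigenvalue (asymptotic annual growth rate λ)."""
    A = matrix.A if isinstance(matrix, ProjectionMatrix) else np.asarray(matrix, float)
    eig = np.linalg.eigvals(A)
    return float(np.max(eig.real[np.abs(eig.imag) < 1e-9]))


def stable_stage_distribution(matrix: ProjectionMatrix | np.ndarray) -> np.ndarray:
    """Right eigenvector of the dominant eigenvalue, normalized to sum 1."""
    A = matrix.A if isinstance(matrix, ProjectionMatrix) else np.asarray(matrix, float)
    vals, vecs = np.linalg.eig(A)
    k = int(np.argmax(vals.real - 1e6 * (np.abs(vals.imag) > 1e-9)))
    v = vecs[:, k].real
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    total = v.sum()
    if total <= 0 or not np.all(np.isfinite(v)):
        raise np.linalg.LinAlgError("degenerate dominant eigenvector")
    v = v / total
    lam = dominant_lambda(A)
    if np.max(np.abs(A @ v - lam * v)) > 1e-8 * max(1.0, lam):
        raise np.linalg.LinAlgError("dominant eigenpair did not converge")
    return v


@dataclass(frozen=True)
class DrawnParameters:
    """One replicate's stochastic inputs: a coefficient draw (held fixed
    within the replicate) and a stream of yearly fecundity multipliers."""

    fit: SurvivalModelFit
    fecundity_multipliers: np.ndarray


def sample_parameters(
    fit: SurvivalModelFit,
    fecundity_sd: float,
    horizon: int,
    seed: int | np.random.Generator,
) -> DrawnParameters:
    """Draw coefficients from the fit's covariance and yearly fecundity noise.

    The coefficient draw is multivariate normal on the logit scale with the
    fit's covariance; fecundity multipliers are lognormal with arithmetic
    mean 1 and SD ``fecundity_sd``.
    """
    if fecundity_sd < 0:
        raise ValueError("fecundity_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = fit.coefficient_covariance
    # fail loudly on a non-PSD covariance rather than silently repairing it
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "coefficient covariance is not positive semi-definite; nearest-PSD "
            "projection (clip negative eigenvalues) would be the remedy"
        ) from exc
    beta = fit.beta + chol @ rng.standard_normal(cov.shape[0])
    if fecundity_sd == 0:
        mult = np.ones(horizon)
    else:
        sigma2 = np.log1p(fecundity_sd**2)
        mult = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=horizon)
    return DrawnParameters(fit=fit.with_beta(beta), fecundity_multipliers=mult)


def calibrate_baseline(
    fit: SurvivalModelFit,
    fecundity_shape: Sequence[float] = DEFAULT_FECUNDITY_SHAPE,
    s_neo: float = 0.65,
    target_lambda: float = 1.015,
    m_mean: float = 0.07,
    birth_sex_ratio: float = 0.5,
    stage_map: StageMap = DEFAULT_STAGE_MAP,
) -> VitalRateSchedule:
    """Scale the relative fecundity schedule so deterministic λ at ``m_mean``
    equals ``target_lambda``.

    λ is monotone increasing in the fecundity scalar, so Brent's method on
    the scalar converges; the survival-only matrix bounds the reachable λ
    from below.
    """
    base = schedule_from_fit(
        fit, fecundity_shape, s_neo=s_neo, m_mean=m_mean,
        birth_sex_ratio=birth_sex_ratio, stage_map=stage_map,
    )
    floor = dominant_lambda(build_matrix(base.with_fecundity_scale(0.0)))
    if target_lambda <= floor:
        raise ValueError(
            f"target lambda {target_lambda} unreachable: survival-only growth is {floor:.4f}"
        )

    def gap(scale: float) -> float:
        return dominant_lambda(build_matrix(base.with_fecundity_scale(scale))) - target_lambda

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target lambda unreachable within fecundity bracket")
    scale = optimize.brentq(gap, 0.0, hi, xtol=1e-10)
    sched = base.with_fecundity_scale(scale)
    lam = dominant_lambda(build_matrix(sched))
    if abs(lam - target_lambda) > 1e-6:
        raise RuntimeError(f"calibration missed target: {lam} vs {target_lambda}")
    return sched


def adjusted_matrix(
    matrix: ProjectionMatrix,
    factors: Mapping[Stage, float],
    fecundity_multiplier: float = 1.0,
) -> np.ndarray:
    """Matrix with survival entries rescaled by their stage's change factor
    (clipped to [0, 1]) and fertility entries by the neonate factor times
    the year's fecundity multiplier."""
    A = matrix.A.copy()
    for (i, j), stage in matrix.entry_stage.items():
        A[i, j] = min(1.0, A[i, j] * float(factors.get(stage, 1.0)))
    neo = float(factors.get(Stage.NEONATE, 1.0)) * float(fecundity_multiplier)
    A[matrix.fertility_mask] *= neo
    return A


def project_one_year(
    state: np.ndarray,
    matrix: ProjectionMatrix,
    factors: Mapping[Stage, float] | None = None,
    fecundity_multiplier: float = 1.0,
) -> np.ndarray:
    """Advance the population one year under scenario change factors."""
    state = np.asarray(state, float)
    if np.any(state < 0):
        raise ValueError("population state has negative entries")
    if factors is None and fecundity_multiplier == 1.0:
        return matrix.A @ state
    A = adjusted_matrix(matrix, factors or {}, fecundity_multiplier)
    return A @ state


def largest_remainder_round(vector: np.ndarray, total: int) -> np.ndarray:
    """Integer abundances summing to ``total``, proportional to ``vector``."""
    vector = np.asarray(vector, float)
    target = vector / vector.sum() * total
    floors = np.floor(target)
    leftover = int(round(total - floors.sum()))
    order = np.argsort(-(target - floors))
    floors[order[:leftover]] += 1
    return floors
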
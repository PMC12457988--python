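"""Sex- and age-class structure of the mountain goat life cycle.

Survival is modeled as piecewise-constant over *life stages* (sex- and
age-categories): a pooled yearling, subadult and young-adult stage, and
sex-specific prime-age ("adult") and old stages.  Neonates (first year of
life) are handled separately — their survival enters the projection model
through the recruitment terms and a dedicated logit line.

The default age boundaries place first reproduction and senescence where
long-term coastal Alaska monitoring places them; they are configurable via
:class:`StageMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Stage(str, Enum):
    NEONATE = "neonate"
    YEARLING = "yearling"
    SUBADULT = "subadult"
    YOUNG_ADULT = "young_adult"
    ADULT_FEMALE = "adult_female"
    ADULT_MALE = "adult_male"
    OLD_FEMALE = "old_female"
    OLD_MALE = "old_male"


#: stages whose survival is estimated from known-fate records (all but neonate)
MODELED_STAGES: tuple[Stage, ...] = (
    Stage.YEARLING,
    Stage.SUBADULT,
    Stage.YOUNG_ADULT,
    Stage.ADULT_FEMALE,
    Stage.ADULT_MALE,
    Stage.OLD_FEMALE,
    Stage.OLD_MALE,
)

#: reference category of the survival model (no offset)
REFERENCE_STAGE: Stage = Stage.OLD_MALE

#: non-reference stages, in the fixed order used for coefficient vectors
OFFSET_STAGES: tuple[Stage, ...] = (
    Stage.YEARLING,
    Stage.SUBADULT,
    Stage.YOUNG_ADULT,
    Stage.ADULT_FEMALE,
    Stage.ADULT_MALE,
    Stage.OLD_FEMALE,
)

#: number of age classes per sex in the projection model
N_AGE_CLASSES = 20
MAX_AGE = N_AGE_CLASSES - 1


class StageConfigError(ValueError):
    """Raised for inconsistent stage/age configuration."""


@dataclass(frozen=True)
class StageMap:
    """Maps (sex, age in years) to a life stage.

    Ages partition 0..19 within each sex: neonate = age 0, then yearling,
    subadult, a young-adult span, a prime-age adult span (sex-specific
    stage), and an old span up to the terminal age class.
    """

    yearling_age: int = 1
    subadult_age: int = 2
    young_adult_ages: tuple[int, int] = (3, 5)
    adult_ages: tuple[int, int] = (6, 8)
    old_ages: tuple[int, int] = (9, MAX_AGE)

    def __post_init__(self) -> None:
        seq = [
            0,
            self.yearling_age,
            self.subadult_age,
            *self.young_adult_ages,
            *self.adult_ages,
            *self.old_ages,
        ]
        expected = [
            0,
            1,
            2,
            3,
            self.young_adult_ages[1],
            self.young_adult_ages[1] + 1,
            self.adult_ages[1],
            self.adult_ages[1] + 1,
            self.old_ages[1],
        ]
        if seq != expected or self.old_ages[1] != MAX_AGE:
            raise StageConfigError(
                f"age ranges must partition 0..{MAX_AGE}: got {seq!r}"
            )

    def stage_of(self, sex: Sex, age: int) -> Stage:
        """Life stage of an animal of the given sex and age (years)."""
        if not 0 <= age <= MAX_AGE:
            raise StageConfigError(f"age {age} outside 0..{MAX_AGE}")
        sex = Sex(sex)
        if age == 0:
            return Stage.NEONATE
        if age == self.yearling_age:
            return Stage.YEARLING
        if age == self.subadult_age:
            return Stage.SUBADULT
        if self.young_adult_ages[0] <= age <= self.young_adult_ages[1]:
            return Stage.YOUNG_ADULT
        if self.adult_ages[0] <= age <= self.adult_ages[1]:
            return Stage.ADULT_FEMALE if sex is Sex.FEMALE else Stage.ADULT_MALE
        return Stage.OLD_FEMALE if sex is Sex.FEMALE else Stage.OLD_MALE

    def projection_stage_of(self, sex: Sex, age: int) -> Stage:
        """Stage whose survival line drives the age→age+1 matrix transition.

        Identical to :meth:`stage_of` except at age 0: first-year (neonate)
        survival is folded into the recruitment entries of the projection
        matrix, so class-0 animals are recruits entering their yearling year
        and their transition uses the yearling line.
        """
        if age == 0:
            return Stage.YEARLING
        return self.stage_of(sex, age)

    def ages_of(self, sex: Sex, stage: Stage) -> list[int]:
        """All ages of the given sex mapped to ``stage``."""
        return [a for a in range(N_AGE_CLASSES) if self.stage_of(sex, a) is stage]


DEFAULT_STAGE_MAP = StageMap()
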
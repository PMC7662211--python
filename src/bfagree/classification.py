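"""Nutritional-status classification and age-quartile grouping.

Two parallel classifications are used when profiling a cohort:

* **BMI-based (WHO)** — normal weight below 25 kg/m², overweight in
  [25, 30), obesity at 30 and above.  Underweight subjects are folded
  into the normal-weight bin so the three categories partition any
  cohort.
* **BF%-based** — sex-specific cut-offs for Caucasian adults applied to
  an estimated body-fat percentage (typically CUN-BAE): women are normal
  at ≤30%, overweight in (30, 35], obese above 35; men use 20/25 as the
  corresponding edges.  The published cut-offs leave sub-0.1% gaps at
  the anchors; bins are closed on the right so every finite value maps
  to exactly one category.

Age groups for stratified analyses are the sample quartiles, with break
values rounded to whole years and boundary ages assigned to the lower
group (after flooring to integer years), matching the convention of
labelling groups "<=b1", "b1+1-b2", ....
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .equations import Sex

__all__ = [
    "NutritionalCategory",
    "AgeGroupScheme",
    "classify_bmi",
    "classify_bf",
    "build_age_groups",
    "assign_age_group",
]


class NutritionalCategory(str, enum.Enum):
    normal_weight = "normal_weight"
    overweight = "overweight"
    obesity = "obesity"


# ordered for monotonicity checks
_CATEGORY_ORDER = (
    NutritionalCategory.normal_weight,
    NutritionalCategory.overweight,
    NutritionalCategory.obesity,
)

# BF% bin edges per sex: normal <= e1 < overweight <= e2 < obesity
_BF_EDGES = {Sex.female: (30.0, 35.0), Sex.male: (20.0, 25.0)}


def classify_bmi(bmi: float) -> NutritionalCategory:
    """WHO BMI category; half-open bins [25, 30) and [30, inf)."""
    if not math.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"bmi must be finite and > 0, got {bmi!r}")
    if bmi < 25.0:
        return NutritionalCategory.normal_weight
    if bmi < 30.0:
        return NutritionalCategory.overweight
    return NutritionalCategory.obesity


def classify_bf(bf_pct: float, sex: Sex) -> NutritionalCategory:
    """Sex-specific body-fat category, bins closed on the right."""
    if not math.isfinite(bf_pct):
        raise ValueError(f"bf_pct must be finite, got {bf_pct!r}")
    e1, e2 = _BF_EDGES[Sex(sex)]
    if bf_pct <= e1:
        return NutritionalCategory.normal_weight
    if bf_pct <= e2:
        return NutritionalCategory.overweight
    return NutritionalCategory.obesity


def classify_bmi_array(bmi: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_bmi`; returns an object array of categories."""
    bmi = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(bmi)) or np.any(bmi <= 0):
        raise ValueError("bmi must be finite and > 0")
    idx = np.digitize(bmi, [25.0, 30.0], right=False)
    return np.array(_CATEGORY_ORDER, dtype=object)[idx]


def classify_bf_array(bf_pct: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_bf` over paired BF% and sex arrays."""
    bf_pct = np.asarray(bf_pct, dtype=float)
    if not np.all(np.isfinite(bf_pct)):
        raise ValueError("bf_pct must be finite")
    female = np.asarray([Sex(s) is Sex.female for s in np.asarray(sex)])
    e1 = np.where(female, 30.0, 20.0)
    e2 = np.where(female, 35.0, 25.0)
    idx = (bf_pct > e1).astype(int) + (bf_pct > e2).astype(int)
    return np.array(_CATEGORY_ORDER, dtype=object)[idx]


@dataclass(frozen=True)
class AgeGroupScheme:
    """Quartile-based age grouping: three integer breaks, four labels."""

    breaks: tuple[int, int, int]
    labels: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if not (self.breaks[0] < self.breaks[1] < self.breaks[2]):
            raise ValueError(f"age breaks must be strictly increasing, got {self.breaks}")
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need exactly one more label than breaks")


def _default_labels(breaks: Sequence[int]) -> tuple[str, str, str, str]:
    b1, b2, b3 = breaks
    return (f"<={b1}", f"{b1 + 1}-{b2}", f"{b2 + 1}-{b3}", f">={b3 + 1}")


def build_age_groups(ages: Sequence[float]) -> AgeGroupScheme:
    """Quartile age-group scheme from a sample of ages.

    Breaks are the 25th/50th/75th percentiles rounded to whole years
    (half away from zero).  Degenerate samples whose quartiles coincide
    raise rather than silently merging groups.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 ages to build quartile groups")
    q = np.percentile(ages, [25.0, 50.0, 75.0])
    breaks = tuple(int(math.floor(x + 0.5)) for x in q)
    if not (breaks[0] < breaks[1] < breaks[2]):
        raise ValueError(
            f"age quartiles are not distinct ({breaks}); cannot form four groups"
        )
    return AgeGroupScheme(breaks=breaks, labels=_default_labels(breaks))


def scheme_from_breaks(breaks: Sequence[int]) -> AgeGroupScheme:
    """Scheme with user-pinned integer breaks (e.g. 32, 40, 48)."""
    b = tuple(int(x) for x in breaks)
    if len(b) != 3:
        raise ValueError("exactly three breaks required")
    return AgeGroupScheme(breaks=b, labels=_default_labels(b))


def assign_age_group(age: float, scheme: AgeGroupScheme) -> str:
    """Label for one age; boundary ages go to the lower group.

    Ages are floored to integer years for the comparison only, so an age
    of 32.7 with breaks (32, 40, 48) still falls in the first group.
    """
    a = math.floor(age)
    b1, b2, b3 = scheme.breaks
    if a <= b1:
        return scheme.labels[0]
    if a <= b2:
        return scheme.labels[1]
    if a <= b3:
        return scheme.labels[2]
    return scheme.labels[3]


def assign_age_group_array(ages: np.ndarray, scheme: AgeGroupScheme) -> np.ndarray:
    """Vectorised :func:`assign_age_group`."""
    floored = np.floor(np.asarray(ages, dtype=float))
    idx = np.digitize(floored, scheme.breaks, right=True)
    return np.array(scheme.labels, dtype=object)[idx]
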
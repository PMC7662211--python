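"""Anthropometric body-fat prediction equations.

Five published equations estimate body-fat percentage (BF%) from routine
anthropometry — age, sex, body-mass index (BMI), height and waist
circumference (WC):

* **CUN-BAE** — the Clínica Universidad de Navarra Body Adiposity
  Estimator, a nine-term polynomial in age, sex and BMI; the reference
  method in the downstream agreement analysis.
* **ECORE-BF** — a three-component equation in age, sex and ln(BMI).
* **RFM** — relative fat mass, built on the height-to-waist ratio and sex.
* **Palafolls** — BMI, the BMI/WC ratio and sex.
* **Deurenberg** — a linear equation in BMI, age and sex.

Sex coding is equation-specific and a classic source of silent errors:
CUN-BAE, ECORE-BF, RFM and Palafolls code women = 1 and men = 0, while
Deurenberg codes men = 1 and women = 0.  Callers therefore pass a
:class:`Sex` enumeration everywhere; the numeric code exists only inside
:func:`sex_code`.

All public equation functions accept scalars or NumPy arrays for the
numeric arguments and return percent body fat.  Units: age in years,
height and WC in centimeters, BMI in kg/m².
"""

from __future__ import annotations

import enum
import logging
from typing import Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "EQUATIONS",
    "AnthropometricRecord",
    "BodyFatPanel",
    "compute_bmi",
    "sex_code",
    "cun_bae",
    "ecore_bf",
    "rfm",
    "palafolls",
    "deurenberg",
    "compute_panel",
]

ArrayLike = Union[float, np.ndarray]

#: Canonical equation identifiers, in the order tables report them.
EQUATIONS = ("cun_bae", "ecore_bf", "rfm", "palafolls", "deurenberg")


class Sex(str, enum.Enum):
    """Biological sex as recorded in the cohort (two values)."""

    female = "female"
    male = "male"


# women = 1 for every equation except Deurenberg, which reverses the coding
_SEX_CODES: dict[str, dict[Sex, int]] = {
    "cun_bae": {Sex.female: 1, Sex.male: 0},
    "ecore_bf": {Sex.female: 1, Sex.male: 0},
    "rfm": {Sex.female: 1, Sex.male: 0},
    "palafolls": {Sex.female: 1, Sex.male: 0},
    "deurenberg": {Sex.female: 0, Sex.male: 1},
}


def sex_code(equation: str, sex: Sex) -> int:
    """Return the 0/1 dummy the given equation uses for ``sex``.

    Raises
    ------
    KeyError
        If ``equation`` is not one of :data:`EQUATIONS`.
    """
    try:
        table = _SEX_CODES[equation]
    except KeyError:
        raise KeyError(
            f"unknown equation {equation!r}; expected one of {EQUATIONS}"
        ) from None
    return table[Sex(sex)]


def compute_bmi(weight_kg: ArrayLike, height_cm: ArrayLike) -> ArrayLike:
    """Body-mass index, weight (kg) over squared height (m²)."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0):
        raise ValueError("weight_kg must be > 0")
    if np.any(height_cm <= 0):
        raise ValueError("height_cm must be > 0")
    out = weight_kg / (height_cm / 100.0) ** 2
    return out if out.ndim else float(out)


def _check_finite(**named: ArrayLike) -> None:
    for name, value in named.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite")


def _coded(equation: str, sex: Union[Sex, np.ndarray]) -> ArrayLike:
    """Sex dummy for an equation; accepts a Sex or an array of Sex/str."""
    if isinstance(sex, (Sex, str)):
        return float(sex_code(equation, Sex(sex)))
    arr = np.asarray(sex)
    return np.array([sex_code(equation, Sex(s)) for s in arr], dtype=float)


def cun_bae(age_years: ArrayLike, sex: Union[Sex, np.ndarray], bmi: ArrayLike) -> ArrayLike:
    """CUN-BAE body-fat percent (nine-term polynomial in age, sex, BMI)."""
    age = np.asarray(age_years, dtype=float)
    b = np.asarray(bmi, dtype=float)
    _check_finite(age_years=age, bmi=b)
    if np.any(b <= 0):
        raise ValueError("bmi must be > 0")
    if np.any(age < 0):
        raise ValueError("age_years must be >= 0")
    s = _coded("cun_bae", sex)
    out = (
        -44.988
        + 0.503 * age
        + 10.689 * s
        + 3.172 * b
        - 0.026 * b**2
        + 0.181 * b * s
        - 0.02 * b * age
        - 0.005 * b**2 * s
        + 0.00021 * b**2 * age
    )
    return out if np.ndim(out) else float(out)


def ecore_bf(age_years: ArrayLike, sex: Union[Sex, np.ndarray], bmi: ArrayLike) -> ArrayLike:
    """ECORE-BF body-fat percent (age, sex, natural log of BMI)."""
    age = np.asarray(age_years, dtype=float)
    b = np.asarray(bmi, dtype=float)
    _check_finite(age_years=age, bmi=b)
    if np.any(b <= 0):
        raise ValueError("bmi must be > 0 (log domain)")
    s = _coded("ecore_bf", sex)
    out = -97.102 + 0.123 * age + 11.900 * s + 35.959 * np.log(b)
    return out if np.ndim(out) else float(out)


def rfm(height_cm: ArrayLike, wc_cm: ArrayLike, sex: Union[Sex, np.ndarray]) -> ArrayLike:
    """Relative fat mass, from the height/WC ratio (both in cm) and sex."""
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(wc_cm, dtype=float)
    _check_finite(height_cm=h, wc_cm=w)
    if np.any(w <= 0):
        raise ValueError("wc_cm must be > 0 (division)")
    s = _coded("rfm", sex)
    out = 64.0 - 20.0 * (h / w) + 12.0 * s
    return out if np.ndim(out) else float(out)


def palafolls(bmi: ArrayLike, wc_cm: ArrayLike, sex: Union[Sex, np.ndarray]) -> ArrayLike:
    """Palafolls body-fat percent (BMI, BMI/WC ratio with WC in cm, sex)."""
    b = np.asarray(bmi, dtype=float)
    w = np.asarray(wc_cm, dtype=float)
    _check_finite(bmi=b, wc_cm=w)
    if np.any(w <= 0):
        raise ValueError("wc_cm must be > 0 (division)")
    s = _coded("palafolls", sex)
    out = (b / w) * 10.0 + b + 10.0 * s
    return out if np.ndim(out) else float(out)


def deurenberg(bmi: ArrayLike, age_years: ArrayLike, sex: Union[Sex, np.ndarray]) -> ArrayLike:
    """Deurenberg body-fat percent; note the reversed sex coding (men = 1)."""
    b = np.asarray(bmi, dtype=float)
    age = np.asarray(age_years, dtype=float)
    _check_finite(bmi=b, age_years=age)
    if np.any(b <= 0):
        raise ValueError("bmi must be > 0")
    s = _coded("deurenberg", sex)
    out = 1.20 * b + 0.23 * age - 10.8 * s - 5.4
    return out if np.ndim(out) else float(out)


class AnthropometricRecord(BaseModel):
    """One subject's anthropometry.

    BMI is always recomputed from weight and height; a supplied ``bmi``
    disagreeing with the recomputed value by more than 0.1 kg/m² is
    logged and replaced (single source of truth).  Ages outside the
    occupational-protocol window 18–65 years are accepted but flagged
    via :attr:`in_protocol`.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    sex: Sex
    age_years: float = Field(ge=0)
    weight_kg: float = Field(gt=0)
    height_cm: float = Field(gt=0)
    wc_cm: float = Field(gt=0)
    bmi: float | None = None

    @model_validator(mode="after")
    def _derive_bmi(self) -> "AnthropometricRecord":
        derived = compute_bmi(self.weight_kg, self.height_cm)
        if self.bmi is not None and abs(self.bmi - derived) > 0.1:
            logger.warning(
                "record %s: supplied bmi %.2f disagrees with recomputed %.2f; "
                "using recomputed value",
                self.id,
                self.bmi,
                derived,
            )
        object.__setattr__(self, "bmi", derived)
        return self

    @property
    def in_protocol(self) -> bool:
        """Whether the age satisfies the 18–65 year inclusion window."""
        return 18.0 <= self.age_years <= 65.0


class BodyFatPanel(BaseModel):
    """The five BF% estimates for one subject, in percent."""

    model_config = ConfigDict(frozen=True)

    cun_bae_pct: float
    ecore_bf_pct: float
    rfm_pct: float
    palafolls_pct: float
    deurenberg_pct: float


_PLAUSIBLE_BF = (0.0, 60.0)


def compute_panel(record: AnthropometricRecord) -> BodyFatPanel:
    """Evaluate all five equations on one validated record.

    Per-equation failures are collected and re-raised with the equation
    names attached.  Values outside the physiologically plausible 0–60%
    band are reported as computed but logged.
    """
    results: dict[str, float] = {}
    failures: dict[str, str] = {}
    calls = {
        "cun_bae": lambda: cun_bae(record.age_years, record.sex, record.bmi),
        "ecore_bf": lambda: ecore_bf(record.age_years, record.sex, record.bmi),
        "rfm": lambda: rfm(record.height_cm, record.wc_cm, record.sex),
        "palafolls": lambda: palafolls(record.bmi, record.wc_cm, record.sex),
        "deurenberg": lambda: deurenberg(record.bmi, record.age_years, record.sex),
    }
    for name, call in calls.items():
        try:
            results[name] = call()
        except ValueError as exc:  # keep going: report every failing equation
            failures[name] = str(exc)
    if failures:
        detail = "; ".join(f"{k}: {v}" for k, v in failures.items())
        raise ValueError(f"equation evaluation failed for record {record.id}: {detail}")
    for name, value in results.items():
        if not _PLAUSIBLE_BF[0] <= value <= _PLAUSIBLE_BF[1]:
            logger.warning(
                "record %s: %s BF%% %.2f outside plausible range %s",
                record.id,
                name,
                value,
                _PLAUSIBLE_BF,
            )
    return BodyFatPanel(
        cun_bae_pct=results["cun_bae"],
        ecore_bf_pct=results["ecore_bf"],
        rfm_pct=results["rfm"],
        palafolls_pct=results["palafolls"],
        deurenberg_pct=results["deurenberg"],
    )
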
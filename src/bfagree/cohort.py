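"""Seeded synthetic occupational cohorts.

The agreement analysis was designed for a large occupational-health
cohort whose raw records are not publicly deposited.  This module
generates a synthetic stand-in: per sex, the joint distribution of
(age, height, BMI, waist circumference) is a truncated multivariate
normal whose marginal means and SDs are calibrated to the published
per-sex descriptive statistics, with a physiologically plausible
correlation structure (BMI–WC strongly positive, weak age effects, a
weak negative height–BMI relation).  Weight is derived from BMI and
height rather than simulated, because BMI and WC are the inputs that
drive every body-fat equation downstream.

Truncation is by rejection sampling, not clipping, so marginal shapes
stay smooth; bounds (age 18–65, the occupational inclusion window, plus
wide plausibility bounds on height/BMI/WC) cut only far tails, so the
induced bias in means is small.  A single integer seed drives one
generator; sex assignment, then the female block, then the male block
consume from it in that fixed order, making cohorts bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .equations import AnthropometricRecord, Sex

__all__ = [
    "MeanSD",
    "SexBlock",
    "CohortSimConfig",
    "default_config",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "frame_to_records",
    "records_to_frame",
    "config_hash",
]

#: Variable order used throughout: rows/columns of `corr`, keys of `bounds`.
VARIABLES = ("age", "height", "bmi", "wc")

COHORT_COLUMNS = ("id", "sex", "age_years", "weight_kg", "height_cm", "wc_cm")

_SEX_TOKENS = {
    "f": Sex.female,
    "female": Sex.female,
    "m": Sex.male,
    "male": Sex.male,
}


class MeanSD(BaseModel):
    model_config = ConfigDict(frozen=True)
    mean: float
    sd: float = Field(gt=0)


class SexBlock(BaseModel):
    """Marginal mean/SD per variable for one sex."""

    model_config = ConfigDict(frozen=True)
    age: MeanSD
    height: MeanSD
    bmi: MeanSD
    wc: MeanSD

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        means = np.array([getattr(self, v).mean for v in VARIABLES])
        sds = np.array([getattr(self, v).sd for v in VARIABLES])
        return means, sds


class CohortSimConfig(BaseModel):
    """Full simulation configuration; JSON-serialisable."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    prop_female: float = Field(gt=0, lt=1)
    female: SexBlock
    male: SexBlock
    corr: tuple[tuple[float, float, float, float], ...]
    bounds: dict[str, tuple[float, float]]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSimConfig":
        c = np.asarray(self.corr, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("corr must be 4x4 over (age, height, bmi, wc)")
        if not np.allclose(c, c.T):
            raise ValueError("corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) <= 0:
            raise ValueError("corr must be positive definite")
        if set(self.bounds) != set(VARIABLES):
            raise ValueError(f"bounds must cover exactly {VARIABLES}")
        for block in (self.female, self.male):
            for v in VARIABLES:
                lo, hi = self.bounds[v]
                if not lo < getattr(block, v).mean < hi:
                    raise ValueError(f"bounds for {v} must contain the mean")
        return self

    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.corr, dtype=float)


def _corr_tuple(m: Mapping[tuple[str, str], float]) -> tuple[tuple[float, ...], ...]:
    c = np.eye(4)
    for (a, b), v in m.items():
        i, j = VARIABLES.index(a), VARIABLES.index(b)
        c[i, j] = c[j, i] = v
    return tuple(tuple(row) for row in c)


def default_config(n: int = 100_000, seed: int = 0) -> CohortSimConfig:
    """Configuration calibrated to the published per-sex descriptives.

    Women: age 39.4 (10.5) y, height 161.7 (6.5) cm, BMI 25.2 (5.0)
    kg/m², WC 75.9 (8.2) cm.  Men: age 40.4 (10.7) y, height 174.4 (7.0)
    cm, BMI 26.7 (4.3) kg/m², WC 88.7 (8.9) cm.  41.7% women.
    """
    corr = _corr_tuple(
        {
            ("bmi", "wc"): 0.85,
            ("age", "wc"): 0.25,
            ("age", "bmi"): 0.20,
            ("height", "wc"): 0.10,
            ("height", "bmi"): -0.05,
            ("age", "height"): -0.10,
        }
    )
    return CohortSimConfig(
        n=n,
        prop_female=0.417,
        female=SexBlock(
            age=MeanSD(mean=39.4, sd=10.5),
            height=MeanSD(mean=161.7, sd=6.5),
            bmi=MeanSD(mean=25.2, sd=5.0),
            wc=MeanSD(mean=75.9, sd=8.2),
        ),
        male=SexBlock(
            age=MeanSD(mean=40.4, sd=10.7),
            height=MeanSD(mean=174.4, sd=7.0),
            bmi=MeanSD(mean=26.7, sd=4.3),
            wc=MeanSD(mean=88.7, sd=8.9),
        ),
        corr=corr,
        bounds={
            "age": (18.0, 65.0),
            "height": (140.0, 200.0),
            "bmi": (15.0, 50.0),
            "wc": (55.0, 140.0),
        },
        seed=seed,
    )


def _sample_truncated(
    rng: np.random.Generator,
    n: int,
    block: SexBlock,
    corr: np.ndarray,
    bounds: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    """Rejection-sample n rows of (age, height, bmi, wc) within bounds."""
    if n == 0:
        return np.empty((0, 4))
    means, sds = block.moments()
    cov = corr * np.outer(sds, sds)
    lo = np.array([bounds[v][0] for v in VARIABLES])
    hi = np.array([bounds[v][1] for v in VARIABLES])
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        draw = rng.multivariate_normal(means, cov, size=max(n - got, 1024) * 2)
        keep = draw[np.all((draw >= lo) & (draw <= hi), axis=1)]
        if keep.shape[0] < draw.shape[0] * 0.01:
            raise ValueError(
                "truncation bounds reject >99% of draws; configuration infeasible"
            )
        out.append(keep)
        got += keep.shape[0]
    return np.concatenate(out)[:n]


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Generate a cohort as a DataFrame on the cohort CSV schema plus bmi.

    Deterministic given ``config.seed``: sex assignment, then the female
    block, then the male block draw from a single generator in that
    order.  Weight is derived as bmi × (height/100)².
    """
    rng = np.random.default_rng(config.seed)
    corr = config.corr_matrix()
    is_female = rng.random(config.n) < config.prop_female
    n_f = int(is_female.sum())
    women = _sample_truncated(rng, n_f, config.female, corr, config.bounds)
    men = _sample_truncated(rng, config.n - n_f, config.male, corr, config.bounds)

    data = np.empty((config.n, 4))
    data[is_female] = women
    data[~is_female] = men

    age, height, bmi, wc = data.T
    weight = bmi * (height / 100.0) ** 2
    width = max(len(str(config.n)), 1)
    return pd.DataFrame(
        {
            "id": [f"S{i:0{width}d}" for i in range(config.n)],
            "sex": np.where(is_female, Sex.female.value, Sex.male.value),
            "age_years": age,
            "weight_kg": weight,
            "height_cm": height,
            "wc_cm": wc,
            "bmi": bmi,
        }
    )


def records_to_frame(records: Iterable[AnthropometricRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "sex": r.sex.value,
            "age_years": r.age_years,
            "weight_kg": r.weight_kg,
            "height_cm": r.height_cm,
            "wc_cm": r.wc_cm,
            "bmi": r.bmi,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + ["bmi"])


def frame_to_records(frame: pd.DataFrame) -> list[AnthropometricRecord]:
    return [
        AnthropometricRecord(
            id=str(row.id),
            sex=Sex(row.sex),
            age_years=float(row.age_years),
            weight_kg=float(row.weight_kg),
            height_cm=float(row.height_cm),
            wc_cm=float(row.wc_cm),
        )
        for row in frame.itertuples(index=False)
    ]


def write_cohort(cohort: pd.DataFrame | Iterable[AnthropometricRecord], path: str | Path) -> None:
    """Write a cohort to the CSV schema (id,sex,age_years,weight_kg,height_cm,wc_cm)."""
    if not isinstance(cohort, pd.DataFrame):
        cohort = records_to_frame(cohort)
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort frame missing columns: {missing}")
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def _parse_sex(token: str, row: int, sex_coding: Mapping[str, str] | None) -> Sex:
    t = str(token).strip()
    if t.lower() in _SEX_TOKENS:
        return _SEX_TOKENS[t.lower()]
    if t in {"0", "1"}:
        if sex_coding is None:
            raise ValueError(
                f"row {row}: numeric sex code {t!r} requires an explicit "
                "sex-coding mapping (e.g. {'0': 'male', '1': 'female'})"
            )
        return Sex(sex_coding[t])
    raise ValueError(f"row {row}: unknown sex token {token!r}")


def read_cohort(
    path: str | Path, sex_coding: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a cohort CSV; returns the frame with bmi recomputed.

    Malformed rows are collected and reported together with their
    1-based data row numbers.  Numeric 0/1 sex codes are rejected unless
    an explicit mapping is supplied.
    """
    raw = pd.read_csv(path, dtype={"id": str, "sex": str}, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")

    errors: list[str] = []
    sexes: list[str] = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            sexes.append(_parse_sex(row.sex, i, sex_coding).value)
        except (ValueError, KeyError) as exc:
            errors.append(str(exc))
            sexes.append("")
        for field in ("age_years", "weight_kg", "height_cm", "wc_cm"):
            value = getattr(row, field)
            if not np.isfinite(value):
                errors.append(f"row {i}: {field} is missing or non-finite")
            elif field != "age_years" and value <= 0:
                errors.append(f"row {i}: {field} must be > 0, got {value}")
            elif field == "age_years" and value < 0:
                errors.append(f"row {i}: age_years must be >= 0, got {value}")
    if errors:
        raise ValueError("cohort validation failed:\n" + "\n".join(errors))

    frame = raw.loc[:, list(COHORT_COLUMNS)].copy()
    frame["sex"] = sexes
    for col in ("age_years", "weight_kg", "height_cm", "wc_cm"):
        frame[col] = frame[col].astype(float)
    frame["bmi"] = frame["weight_kg"] / (frame["height_cm"] / 100.0) ** 2
    return frame


def config_hash(config: CohortSimConfig) -> str:
    """Stable short hash of a configuration, for provenance blocks."""
    payload = json.dumps(config.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
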
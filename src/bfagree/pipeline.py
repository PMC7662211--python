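"""End-to-end analysis pipeline.

Orchestrates the full comparison study on a cohort frame: per-subject
body-fat panels, sample descriptives (including the dual BMI-based and
BF%-based nutritional-status prevalences), and the stratified agreement
analysis of each candidate equation against the reference method
(CUN-BAE by default) across ten strata — overall, the two sexes, the
three WHO BMI categories, and four age-quartile groups.

All tables are plain pandas DataFrames; :func:`run_report` writes them
as CSV together with per-equation Bland–Altman plot data and a JSON
provenance block, deterministically for a given input and seed.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    AgreementResult,
    analyze_pair,
    bland_altman_plot_data,
    mean_comparison,
    PairedSeries,
)
from .classification import (
    AgeGroupScheme,
    assign_age_group_array,
    build_age_groups,
    classify_bf_array,
    classify_bmi_array,
    scheme_from_breaks,
)
from .cohort import CohortSimConfig, config_hash, simulate_cohort
from .equations import EQUATIONS, Sex, cun_bae, deurenberg, ecore_bf, palafolls, rfm

__all__ = [
    "StratumType",
    "StratumKey",
    "add_panel_columns",
    "build_strata",
    "run_descriptives",
    "run_agreement",
    "run_report",
]

#: Candidate equations compared against the reference, in table order.
CANDIDATES = ("ecore_bf", "rfm", "palafolls", "deurenberg")

_QUANT_VARS = (
    ("age_years", "Age (years)"),
    ("weight_kg", "Weight (kg)"),
    ("height_cm", "Height (cm)"),
    ("wc_cm", "WC (cm)"),
    ("bmi", "BMI (kg/m2)"),
    ("cun_bae", "CUN-BAE (%)"),
    ("ecore_bf", "ECORE-BF (%)"),
    ("rfm", "RFM (%)"),
    ("palafolls", "Palafolls (%)"),
    ("deurenberg", "Deurenberg (%)"),
)

_CATEGORIES = ("normal_weight", "overweight", "obesity")


class StratumType(str, enum.Enum):
    overall = "overall"
    sex = "sex"
    bmi_category = "bmi_category"
    age_quartile = "age_quartile"


@dataclass(frozen=True)
class StratumKey:
    stratum_type: StratumType
    stratum_label: str


def add_panel_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the five BF% estimate columns appended.

    Vectorised evaluation of the same equations as the per-record panel;
    the two paths agree to machine precision.
    """
    out = frame.copy()
    sex = frame["sex"].to_numpy()
    age = frame["age_years"].to_numpy(dtype=float)
    bmi = frame["bmi"].to_numpy(dtype=float)
    height = frame["height_cm"].to_numpy(dtype=float)
    wc = frame["wc_cm"].to_numpy(dtype=float)
    out["cun_bae"] = cun_bae(age, sex, bmi)
    out["ecore_bf"] = ecore_bf(age, sex, bmi)
    out["rfm"] = rfm(height, wc, sex)
    out["palafolls"] = palafolls(bmi, wc, sex)
    out["deurenberg"] = deurenberg(bmi, age, sex)
    return out


def build_strata(
    frame: pd.DataFrame, age_scheme: AgeGroupScheme | None = None
) -> list[tuple[StratumKey, np.ndarray]]:
    """The ten analysis strata as (key, boolean mask) pairs, in table order."""
    if age_scheme is None:
        age_scheme = build_age_groups(frame["age_years"].to_numpy())
    sex = frame["sex"].to_numpy()
    bmi_cat = classify_bmi_array(frame["bmi"].to_numpy())
    age_group = assign_age_group_array(frame["age_years"].to_numpy(), age_scheme)

    strata: list[tuple[StratumKey, np.ndarray]] = [
        (StratumKey(StratumType.overall, "total"), np.ones(len(frame), dtype=bool))
    ]
    for s in (Sex.female, Sex.male):
        strata.append((StratumKey(StratumType.sex, s.value), sex == s.value))
    for cat in _CATEGORIES:
        strata.append(
            (StratumKey(StratumType.bmi_category, cat), np.array([c.value == cat for c in bmi_cat]))
        )
    for label in age_scheme.labels:
        strata.append((StratumKey(StratumType.age_quartile, label), age_group == label))
    return strata


def run_descriptives(frame: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Sample descriptives overall and by sex.

    Quantitative rows carry mean/SD per group and a two-sided p-value
    for the female-vs-male comparison (pooled-variance t by default);
    category rows carry counts and within-group percentages for both the
    BMI-based and the CUN-BAE BF%-based classifications.
    """
    if len(frame) == 0:
        raise ValueError("empty cohort")
    df = frame if "cun_bae" in frame.columns else add_panel_columns(frame)
    female = df["sex"].to_numpy() == Sex.female.value
    groups = {"total": np.ones(len(df), bool), "female": female, "male": ~female}

    rows: list[dict] = []
    for col, label in _QUANT_VARS:
        row: dict = {"variable": label, "kind": "mean_sd"}
        for g, mask in groups.items():
            x = df.loc[mask, col].to_numpy(dtype=float)
            row[f"{g}_value"] = float(np.mean(x)) if x.size else np.nan
            row[f"{g}_spread"] = float(np.std(x, ddof=1)) if x.size > 1 else np.nan
        xf = df.loc[female, col].to_numpy(dtype=float)
        xm = df.loc[~female, col].to_numpy(dtype=float)
        if xf.size >= 2 and xm.size >= 2 and (np.ptp(xf) > 0 or np.ptp(xm) > 0):
            _t, p = mean_comparison(xf, xm, welch=welch)
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        rows.append(row)

    bmi_cat = np.array([c.value for c in classify_bmi_array(df["bmi"].to_numpy())])
    bf_cat = np.array(
        [c.value for c in classify_bf_array(df["cun_bae"].to_numpy(), df["sex"].to_numpy())]
    )
    for scheme, cats in (("bmi", bmi_cat), ("cun_bae_bf", bf_cat)):
        for cat in _CATEGORIES:
            row = {"variable": f"{scheme}:{cat}", "kind": "count_pct", "p_value": np.nan}
            for g, mask in groups.items():
                n_g = int(mask.sum())
                count = int(np.sum(cats[mask] == cat))
                row[f"{g}_value"] = count
                row[f"{g}_spread"] = 100.0 * count / n_g if n_g else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


_NA_COLS = (
    "pearson_r",
    "ccc",
    "ccc_l95",
    "ccc_u95",
    "mean_diff",
    "sd_diff",
    "loa_low",
    "loa_high",
)


def run_agreement(
    frame: pd.DataFrame,
    reference: str = "cun_bae",
    age_scheme: AgeGroupScheme | None = None,
    age_breaks: Sequence[int] | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Stratified agreement of every other equation against ``reference``.

    One row per (stratum, equation) in fixed table order.  Strata with
    fewer than 3 subjects are emitted with statistics set to NaN rather
    than dropped.
    """
    if reference not in EQUATIONS:
        raise ValueError(f"unknown reference {reference!r}; expected one of {EQUATIONS}")
    if len(frame) == 0:
        raise ValueError("empty cohort")
    df = frame if reference in frame.columns else add_panel_columns(frame)
    if age_breaks is not None:
        age_scheme = scheme_from_breaks(age_breaks)
    candidates = [e for e in EQUATIONS if e != reference]
    # keep the reporting order of the published tables where applicable
    candidates.sort(key=lambda e: (CANDIDATES.index(e) if e in CANDIDATES else -1))

    rows = []
    for key, mask in build_strata(df, age_scheme):
        ref_vals = df.loc[mask, reference].to_numpy(dtype=float)
        for eq in candidates:
            row = {
                "stratum_type": key.stratum_type.value,
                "stratum_label": key.stratum_label,
                "equation": eq,
                "n": int(mask.sum()),
            }
            est = df.loc[mask, eq].to_numpy(dtype=float)
            if est.size < 3:
                row.update({c: np.nan for c in _NA_COLS})
            else:
                res: AgreementResult = analyze_pair(
                    PairedSeries(est, ref_vals, label=eq), ci_level
                )
                row.update(
                    pearson_r=res.pearson_r,
                    ccc=res.ccc,
                    ccc_l95=res.ccc_ci_low,
                    ccc_u95=res.ccc_ci_high,
                    mean_diff=res.mean_diff,
                    sd_diff=res.sd_diff,
                    loa_low=res.loa_low,
                    loa_high=res.loa_high,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def _pivot(agreement: pd.DataFrame, values: Sequence[str]) -> pd.DataFrame:
    wide = agreement.pivot_table(
        index=["stratum_type", "stratum_label"],
        columns="equation",
        values=list(values),
        sort=False,
    )
    wide.columns = [f"{eq}_{stat}" if len(values) > 1 else eq for stat, eq in wide.columns]
    return wide.reset_index()


def run_report(
    frame: pd.DataFrame | None,
    outdir: str | Path,
    config: CohortSimConfig | None = None,
    reference: str = "cun_bae",
    age_breaks: Sequence[int] | None = None,
    ci_level: float = 0.95,
    welch: bool = False,
) -> dict[str, Path]:
    """Run the full analysis and write all report files into ``outdir``.

    Either an existing cohort ``frame`` or a simulation ``config`` must
    be given.  Writes descriptives, the long agreement table, wide
    correlation/concordance/difference analogs, per-equation plot-data
    CSVs with a reference-line sidecar, and a provenance JSON.  Output is
    byte-identical across runs with the same inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not outdir.is_dir():
        raise ValueError(f"not a writable directory: {outdir}")
    if frame is None:
        if config is None:
            raise ValueError("either a cohort frame or a simulation config is required")
        frame = simulate_cohort(config)

    df = add_panel_columns(frame)
    descriptives = run_descriptives(df, welch=welch)
    agreement = run_agreement(df, reference=reference, age_breaks=age_breaks, ci_level=ci_level)

    paths: dict[str, Path] = {}

    def _write(name: str, table: pd.DataFrame) -> None:
        p = outdir / name
        table.to_csv(p, index=False, float_format="%.4f")
        paths[name] = p

    _write("descriptives.csv", descriptives)
    _write("agreement.csv", agreement)
    corr = _pivot(agreement, ["pearson_r"]).round(3)
    ccc = _pivot(agreement, ["ccc", "ccc_l95", "ccc_u95"]).round(3)
    diff = _pivot(agreement, ["mean_diff", "sd_diff", "loa_low", "loa_high"]).round(4)
    _write("correlation.csv", corr)
    _write("concordance.csv", ccc)
    _write("differences.csv", diff)

    lines: dict[str, dict[str, float]] = {}
    for eq in (e for e in EQUATIONS if e != reference):
        table, refs = bland_altman_plot_data(
            df[eq].to_numpy(dtype=float), df[reference].to_numpy(dtype=float)
        )
        _write(f"bland_altman_{eq}.csv", table)
        lines[eq] = {k: round(v, 4) for k, v in refs.items()}
    sidecar = outdir / "bland_altman_lines.json"
    sidecar.write_text(json.dumps(lines, indent=2, sort_keys=True) + "\n")
    paths[sidecar.name] = sidecar

    provenance = {
        "software": "bfagree",
        "version": __version__,
        "n_records": int(len(df)),
        "reference": reference,
        "ci_level": ci_level,
        "age_breaks": list(age_breaks) if age_breaks is not None else None,
        "seed": config.seed if config is not None else None,
        "config_hash": config_hash(config) if config is not None else None,
        "note": "ccc_l95/ccc_u95 are an extension; the source tables report no CCC CIs",
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    paths[prov_path.name] = prov_path
    return paths
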
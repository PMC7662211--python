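"""Method-comparison statistics for paired measurements.

Given paired body-fat estimates from a candidate equation and a
reference method, agreement is summarised three ways:

* Pearson's product-moment correlation ``r`` — linear association only;
  blind to additive or multiplicative bias.
* Lin's concordance correlation coefficient (CCC) — agreement with the
  45° identity line.  With means x̄, ȳ, biased (1/n) variances s²x, s²y
  and covariance s_xy,

      CCC = 2·s_xy / (s²x + s²y + (x̄ − ȳ)²)

  which factorises as r times a bias-correction term in (0, 1], so
  |CCC| ≤ |r| always.  The confidence interval uses the Fisher
  z-transform with Lin's asymptotic variance.
* Bland–Altman analysis — the mean difference (estimate − reference),
  the sample SD of the differences (n − 1 denominator), and the 95%
  limits of agreement at mean ± 1.96 SD.

The 1/n moment convention for the CCC follows Lin's original
definition; it matters in principle because the squared mean shift makes
1/n and 1/(n−1) versions non-equivalent, though at cohort scale the
difference is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementResult",
    "pearson_r",
    "lin_ccc",
    "bland_altman",
    "mean_comparison",
    "bland_altman_plot_data",
    "analyze_pair",
    "format_p",
]

LOA_MULTIPLIER = 1.96  # fixed conventional multiplier, not a t quantile
_MIN_P = 1e-300


@dataclass(frozen=True)
class PairedSeries:
    """Paired candidate/reference measurements for one equation."""

    estimate: np.ndarray
    reference: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        est = np.asarray(self.estimate, dtype=float)
        ref = np.asarray(self.reference, dtype=float)
        if est.shape != ref.shape or est.ndim != 1:
            raise ValueError("estimate and reference must be 1-D of equal length")
        if est.size < 2:
            raise ValueError("need at least 2 pairs")
        if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
            raise ValueError("missing or non-finite values after pairing")
        object.__setattr__(self, "estimate", est)
        object.__setattr__(self, "reference", ref)


@dataclass(frozen=True)
class AgreementResult:
    """Agreement summary for one (equation, stratum) pair."""

    n: int
    pearson_r: float
    ccc: float
    ccc_ci_low: float
    ccc_ci_high: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_level: float = 0.95


def _as_series(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input (undefined)."""
    xa, ya = _as_series(x, "x"), _as_series(y, "y")
    if xa.size != ya.size:
        raise ValueError("series lengths differ")
    if xa.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(xa, ya).statistic)


def lin_ccc(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Lin's CCC with a Fisher-z confidence interval.

    Returns ``(ccc, ci_low, ci_high)``.  For |CCC| numerically at 1 the
    asymptotic variance degenerates and the interval collapses to the
    point estimate.
    """
    xa, ya = _as_series(x, "x"), _as_series(y, "y")
    if xa.size != ya.size:
        raise ValueError("series lengths differ")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("CCC undefined for a constant series")

    mx, my = xa.mean(), ya.mean()
    sx2 = float(np.mean((xa - mx) ** 2))  # 1/n moments, per the definition
    sy2 = float(np.mean((ya - my) ** 2))
    if sx2 == 0.0 or sy2 == 0.0:  # variance underflow: numerically constant
        raise ValueError("CCC undefined for a (numerically) constant series")
    sxy = float(np.mean((xa - mx) * (ya - my)))
    ccc = float(2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2))

    r = sxy / math.sqrt(sx2 * sy2)
    if abs(ccc) >= 1.0 - 1e-15 or abs(r) >= 1.0 - 1e-15:
        return ccc, ccc, ccc

    # Lin's asymptotic variance of z = atanh(CCC)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c2 = ccc**2
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 4 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - 2 * ccc**4 * u**4 / (r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se_z = math.sqrt(max(var_z, 0.0))
    zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
    z = math.atanh(ccc)
    return ccc, math.tanh(z - zcrit * se_z), math.tanh(z + zcrit * se_z)


def bland_altman(
    estimate: Sequence[float], reference: Sequence[float]
) -> tuple[float, float, float, float]:
    """Mean difference, SD of differences and 95% limits of agreement.

    Differences are estimate − reference; SD uses the n − 1 denominator;
    limits are mean ± 1.96 SD.
    """
    est, ref = _as_series(estimate, "estimate"), _as_series(reference, "reference")
    if est.size != ref.size:
        raise ValueError("series lengths differ")
    if est.size < 2:
        raise ValueError("need at least 2 pairs")
    d = est - ref
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return md, sd, md - LOA_MULTIPLIER * sd, md + LOA_MULTIPLIER * sd


def mean_comparison(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p (pooled variance by default)."""
    xa, ya = _as_series(x, "x"), _as_series(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(xa) == 0 and np.ptp(ya) == 0:
        raise ValueError("t-test undefined: zero variance in both groups")
    res = stats.ttest_ind(xa, ya, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bland_altman_plot_data(
    estimate: Sequence[float], reference: Sequence[float]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-pair (mean, difference) points plus reference lines.

    Returns a DataFrame with columns ``pair_mean``/``pair_diff`` (one row
    per pair) and a dict of the horizontal lines ``mean_diff``,
    ``loa_low``, ``loa_high`` for rendering a Bland–Altman scatter.
    """
    est, ref = _as_series(estimate, "estimate"), _as_series(reference, "reference")
    md, _sd, lo, hi = bland_altman(est, ref)
    table = pd.DataFrame({"pair_mean": (est + ref) / 2.0, "pair_diff": est - ref})
    return table, {"mean_diff": md, "loa_low": lo, "loa_high": hi}


def analyze_pair(pair: PairedSeries, ci_level: float = 0.95) -> AgreementResult:
    """All agreement statistics for one paired series."""
    r = pearson_r(pair.estimate, pair.reference)
    ccc, lo, hi = lin_ccc(pair.estimate, pair.reference, ci_level)
    md, sd, loa_lo, loa_hi = bland_altman(pair.estimate, pair.reference)
    return AgreementResult(
        n=int(pair.estimate.size),
        pearson_r=r,
        ccc=ccc,
        ccc_ci_low=lo,
        ccc_ci_high=hi,
        mean_diff=md,
        sd_diff=sd,
        loa_low=loa_lo,
        loa_high=loa_hi,
        ci_level=ci_level,
    )


def format_p(p: float) -> str:
    """Text rendering of a p-value; tiny values print as '<1e-300'."""
    if p < _MIN_P:
        return "<1e-300"
    return f"{p:.3g}"
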
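"""Agreement statistics: ICC(2,1), percentile bootstrap CIs, Bland-Altman.

The reliability harness of the validation study.  The ICC is the two-way
random-effects, single-measures, absolute-agreement coefficient — ICC(A,1)
of McGraw & Wong, identical to Shrout-Fleiss ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with subjects-by-raters mean squares MSR (rows), MSC (columns), MSE
(interaction residual).  Confidence intervals are non-parametric percentile
bootstrap over subjects (the exchangeable unit: one cup placement).  Bland-
Altman limits of agreement are bias +/- 1.96 sd of the paired differences
(sample sd, n-1 denominator); a t-quantile small-sample variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCUndefinedError",
    "ICCResult",
    "BlandAltmanResult",
    "icc_2_1",
    "bootstrap_ci",
    "icc_with_ci",
    "bland_altman",
    "classify_icc",
    "agreement_report",
    "ANALYSES",
]

ANALYSES = ("interrater", "intrarater", "intermethod")


class ICCUndefinedError(ValueError):
    """ICC undefined: the table carries no variance to apportion."""


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    n_boot: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.estimate > 1.0 + 1e-12:
            raise ValueError("ICC cannot exceed 1")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2D subjects x raters table")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(arr)):
        raise ValueError("table contains missing or non-finite values")
    return arr


def _mean_squares(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-way ANOVA mean squares (MSR, MSC, MSE); data is (..., n, k)."""
    n = data.shape[-2]
    k = data.shape[-1]
    grand = data.mean(axis=(-2, -1), keepdims=True)
    row_means = data.mean(axis=-1, keepdims=True)
    col_means = data.mean(axis=-2, keepdims=True)
    msr = k * np.sum((row_means - grand) ** 2, axis=(-2, -1)) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2, axis=(-2, -1)) / (k - 1)
    resid = data - row_means - col_means + grand
    mse = np.sum(resid**2, axis=(-2, -1)) / ((n - 1) * (k - 1))
    return msr, msc, mse


def _icc_from_ms(msr, msc, mse, n: int, k: int):
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom != 0, (msr - mse) / denom, np.nan)


def icc_2_1(table) -> float:
    """ICC(2,1) of a complete subjects-by-raters table.

    Raises :class:`ICCUndefinedError` when the table has zero total variance
    (every cell identical), where the coefficient is 0/0.
    """
    data = _as_table(table)
    n, k = data.shape
    if np.ptp(data) == 0:
        raise ICCUndefinedError(
            "all values identical: no variance, ICC(2,1) is undefined"
        )
    msr, msc, mse = _mean_squares(data)
    value = float(_icc_from_ms(msr, msc, mse, n, k))
    if np.isnan(value):
        raise ICCUndefinedError("zero ANOVA denominator: ICC(2,1) is undefined")
    return value


def _bootstrap_icc_fast(data: np.ndarray, n_boot: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Vectorized subject-resampled ICC replicates (NaN where undefined)."""
    n, k = data.shape
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = data[idx]                       # (B, n, k)
    msr, msc, mse = _mean_squares(samples)
    return _icc_from_ms(msr, msc, mse, n, k)


def bootstrap_ci(
    table,
    statistic: Callable[[np.ndarray], float] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI, resampling subjects (rows) with replacement.

    ``statistic`` maps a resampled table to a scalar; by default it is
    :func:`icc_2_1`, for which a vectorized path is used.  Replicates where
    the statistic is undefined are dropped; if more than half fail the CI is
    refused with an error naming the failure mode.
    """
    data = _as_table(table)
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    if statistic is None or statistic is icc_2_1:
        values = _bootstrap_icc_fast(data, n_boot, rng)
        failure = "ICC undefined (zero variance) in resample"
    else:
        n = data.shape[0]
        values = np.full(n_boot, np.nan)
        failure = "statistic raised an error"
        for b in range(n_boot):
            sample = data[rng.integers(0, n, size=n)]
            try:
                values[b] = statistic(sample)
            except (ValueError, ZeroDivisionError, FloatingPointError):
                pass
    ok = values[np.isfinite(values)]
    if len(ok) < 0.5 * n_boot:
        raise ICCUndefinedError(
            f"bootstrap failed: {failure} in {n_boot - len(ok)}/{n_boot} replicates"
        )
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return float(lo), float(hi)


def icc_with_ci(table, n_boot: int = 2000, seed: int | None = None) -> ICCResult:
    """Point estimate plus bootstrap CI in one result object.

    A percentile CI that fails to contain the point estimate is possible for
    a resampled statistic; it is reported as computed, not clipped.
    """
    data = _as_table(table)
    est = icc_2_1(data)
    lo, hi = bootstrap_ci(data, n_boot=n_boot, seed=seed)
    return ICCResult(estimate=est, ci_low=lo, ci_high=hi,
                     n_subjects=data.shape[0], n_raters=data.shape[1],
                     n_boot=n_boot, seed=seed)


def bland_altman(x: Sequence[float], y: Sequence[float],
                 t_based: bool = False) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement of paired series.

    Differences are ``x - y``; limits are bias +/- 1.96 sd (sample sd).  With
    ``t_based`` the normal quantile is replaced by the two-sided t(0.95,
    n-1) quantile for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 paired values")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mult = float(stats.t.ppf(0.975, len(d) - 1)) if t_based else 1.96
    return BlandAltmanResult(bias=bias, loa_low=bias - mult * sd,
                             loa_high=bias + mult * sd, sd_diff=sd, n=len(d))


def classify_icc(value: float) -> str:
    """Interpretation band: > 0.75 is excellent agreement."""
    if value > 0.75:
        return "excellent"
    if value >= 0.4:
        return "fair to good"
    return "poor"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _series(measurements: pd.DataFrame, angle: str, condition: str,
            rater: int, session: int) -> pd.Series:
    sel = measurements[
        (measurements["angle"] == angle)
        & (measurements["condition"] == condition)
        & (measurements["rater"] == rater)
        & (measurements["session"] == session)
    ]
    return sel.set_index("placement_id")["value"]


def agreement_report(
    measurements: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    analysis: str = "intermethod",
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Six-row agreement table (2 angles x 3 conditions) for one analysis.

    * ``interrater``  — rater 1 vs rater 2, first session of each (only the
      repeating rater's first pass enters, as in the study);
    * ``intrarater``  — rater 1 session 1 vs session 2;
    * ``intermethod`` — rater 1 session 1 vs the 3D reference (truth table).

    Cells with an undefined ICC (zero variance) carry NaN estimates and the
    note in the ``icc_note`` column instead of a fabricated value.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}")
    if analysis == "intermethod" and truth is None:
        raise ValueError("intermethod analysis needs the truth table")

    angles = ("anteversion", "inclination")
    conditions = list(dict.fromkeys(measurements["condition"]))
    gaps: list[str] = []
    rows: list[dict] = []
    for angle in angles:
        for condition in conditions:
            a = _series(measurements, angle, condition, rater=1, session=1)
            if analysis == "interrater":
                b = _series(measurements, angle, condition, rater=2, session=1)
            elif analysis == "intrarater":
                b = _series(measurements, angle, condition, rater=1, session=2)
            else:
                t = truth[truth["condition"] == condition].set_index("placement_id")
                b = t[f"true_{angle}"]
            common = a.index.intersection(b.index)
            if len(common) < 2 or len(a) == 0 or len(b) == 0:
                gaps.append(f"{analysis}/{angle}/{condition}")
                continue
            a, b = a.loc[common], b.loc[common]
            table = np.column_stack([a.to_numpy(), b.to_numpy()])
            note = ""
            try:
                icc = icc_with_ci(table, n_boot=n_boot, seed=seed)
                est, lo, hi = icc.estimate, icc.ci_low, icc.ci_high
            except ICCUndefinedError as exc:
                est = lo = hi = np.nan
                note = str(exc)
            ba = bland_altman(a.to_numpy(), b.to_numpy())
            rows.append({
                "analysis": analysis,
                "angle": angle,
                "condition": condition,
                "n": len(common),
                "icc": est,
                "ci_low": lo,
                "ci_high": hi,
                "bias": ba.bias,
                "loa_low": ba.loa_low,
                "loa_high": ba.loa_high,
                "icc_note": note,
            })
    if gaps:
        raise ValueError("missing measurement series for: " + ", ".join(gaps))
    return pd.DataFrame(rows)


def render_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering, 3 decimals as in printed agreement tables."""
    lines = [f"{'analysis':<12}{'angle':<13}{'condition':<13}"
             f"{'ICC':>8}{'CI low':>9}{'CI high':>9}{'bias':>9}"
             f"{'LoA low':>9}{'LoA high':>9}"]
    for _, r in report.iterrows():
        icc = "undef" if pd.isna(r["icc"]) else f"{r['icc']:.3f}"
        lo = "" if pd.isna(r["ci_low"]) else f"{r['ci_low']:.3f}"
        hi = "" if pd.isna(r["ci_high"]) else f"{r['ci_high']:.3f}"
        lines.append(
            f"{r['analysis']:<12}{r['angle']:<13}{r['condition']:<13}"
            f"{icc:>8}{lo:>9}{hi:>9}{r['bias']:>9.3f}"
            f"{r['loa_low']:>9.3f}{r['loa_high']:>9.3f}"
        )
    return "\n".join(lines)
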
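"""Test-retest reliability statistics over a subjects x repetitions matrix.

ICC(1,1) is the one-way random-effects, single-measurement intraclass
correlation (MSB - MSW) / (MSB + (k-1) MSW) with the exact F-distribution
confidence interval. The per-parameter summary row additionally carries the
grand mean (mean of per-subject means), mean within-subject SD (sample SD,
k-1 divisor), mean CV in percent, and the classification bands used for
reporting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedRatioError


@dataclass
class MeasurementMatrix:
    """n_subjects x k_repetitions values of one parameter; rows containing
    missing cells are removed listwise with a warning."""

    values: np.ndarray
    parameter_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("measurement matrix must be 2-D")
        missing = ~np.isfinite(self.values)
        if missing.any():
            keep = ~missing.any(axis=1)
            warnings.warn(
                f"{self.parameter_name or 'matrix'}: dropping "
                f"{int((~keep).sum())} subject(s) with missing cells"
            )
            self.values = self.values[keep]
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise InputError(f"need >= 2 subjects and >= 2 repetitions, got {n} x {k}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def icc_1_1(m: MeasurementMatrix, ci_level: float = 0.95) -> tuple[float, float, float]:
    """(icc, ci_low, ci_high) from a one-way random-effects ANOVA."""
    x = m.values
    n, k = x.shape
    subject_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * ((subject_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - subject_means[:, None]) ** 2).sum() / (n * (k - 1))
    if msb == 0 and msw == 0:
        raise UndefinedRatioError("all cells identical; ICC undefined")
    if msw == 0:
        return 1.0, 1.0, 1.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    alpha = 1.0 - ci_level
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    low = (fl - 1) / (fl + k - 1)
    high = (fu - 1) / (fu + k - 1)
    return float(icc), float(low), float(high)


def mean_sd(m: MeasurementMatrix) -> float:
    """Per-subject SD across repetitions (k-1 divisor), averaged."""
    return float(m.values.std(axis=1, ddof=1).mean())


def mean_cv(m: MeasurementMatrix) -> float:
    """Per-subject CV = SD / |mean| x 100, averaged; zero-mean subjects are
    excluded with a warning."""
    means = m.values.mean(axis=1)
    sds = m.values.std(axis=1, ddof=1)
    nonzero = means != 0
    if not nonzero.any():
        raise UndefinedRatioError("all subject means are zero; CV undefined")
    if not nonzero.all():
        warnings.warn(
            f"{m.parameter_name or 'matrix'}: excluding "
            f"{int((~nonzero).sum())} zero-mean subject(s) from CV"
        )
    return float((sds[nonzero] / np.abs(means[nonzero]) * 100.0).mean())


def classify_icc(icc: float) -> str:
    if icc >= 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def classify_cv(cv_percent: float) -> str:
    if cv_percent <= 10:
        return "excellent"
    if cv_percent <= 20:
        return "good"
    if cv_percent <= 30:
        return "moderate"
    return "poor"


def classify_sd(sd_px: float) -> str:
    if sd_px <= 1:
        return "very small"
    if sd_px <= 2:
        return "small"
    if sd_px <= 3:
        return "moderate"
    return "large"


@dataclass
class ReliabilityRow:
    parameter_name: str
    units: str
    grand_mean: float
    mean_sd: float
    mean_cv_percent: float
    icc: float
    ci_low: float
    ci_high: float
    icc_band: str
    cv_band: str
    sd_band: str
    n_subjects: int
    k_repetitions: int
    warnings: list[str] = field(default_factory=list)


def reliability_row(m: MeasurementMatrix, ci_level: float = 0.95) -> ReliabilityRow:
    icc, low, high = icc_1_1(m, ci_level)
    sd = mean_sd(m)
    try:
        cv = mean_cv(m)
    except UndefinedRatioError:
        cv = float("nan")
    return ReliabilityRow(
        parameter_name=m.parameter_name,
        units=m.units,
        grand_mean=float(m.values.mean(axis=1).mean()),
        mean_sd=sd,
        mean_cv_percent=cv,
        icc=icc,
        ci_low=low,
        ci_high=high,
        icc_band=classify_icc(icc),
        cv_band=classify_cv(cv) if np.isfinite(cv) else "undefined",
        sd_band=classify_sd(sd),
        n_subjects=m.n,
        k_repetitions=m.k,
    )


def reliability_table(
    matrices: dict[str, MeasurementMatrix],
    pixel_mm: float = 5.1,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """One summary row per parameter, mirroring the published column layout
    (px and mm for pixel-valued parameters)."""
    records = []
    for name, m in matrices.items():
        try:
            row = reliability_row(m, ci_level)
        except (UndefinedRatioError, InputError) as exc:
            records.append({"parameter": name, "units": m.units, "error": str(exc)})
            continue
        px_like = m.units == "px"
        records.append(
            {
                "parameter": name,
                "units": m.units,
                "mean_px": row.grand_mean if px_like else np.nan,
                "mean_mm": row.grand_mean * pixel_mm if px_like else np.nan,
                "mean": row.grand_mean,
                "sd_px": row.mean_sd if px_like else np.nan,
                "sd_mm": row.mean_sd * pixel_mm if px_like else np.nan,
                "sd": row.mean_sd,
                "cv_percent": row.mean_cv_percent,
                "icc": row.icc,
                "ci_low": row.ci_low,
                "ci_high": row.ci_high,
                "icc_band": row.icc_band,
                "cv_band": row.cv_band,
                "sd_band": row.sd_band,
                "error": "",
            }
        )
    return pd.DataFrame.from_records(records).set_index("parameter")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(json.loads(table.to_json(orient="index")), indent=2, sort_keys=True) + "\n")
    else:
        table.to_csv(path)
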
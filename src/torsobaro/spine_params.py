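"""Frontal spine curve (FC1-FC7) and sagittal profile parameters (SC1-SC8).

The frontal curve follows the concave intensity canal over the spinous
processes: per row the local minimum closest to the symmetry axis inside
the central band, smoothed by a fifth-degree polynomial. The sagittal
parameters are slope angles and intensity ratios of the profile z(j) over
the thoracic and lumbar regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import FitError, UndefinedRatioError
from .landmarks import LandmarkSet
from .preprocess import RoiImage


@dataclass
class FrontalCurve:
    rows: np.ndarray  # integer rows jt..jl
    curve: np.ndarray  # Lfc evaluated on rows
    line: np.ndarray  # linear fit Lfc_s on rows
    slope: float  # slope coefficient of the linear fit
    intercept: float
    raw_rows: np.ndarray  # rows with a detected canal minimum
    raw_minima: np.ndarray  # selected minimum column per raw row
    coeffs: np.ndarray  # fifth-degree polynomial coefficients (ascending)


@dataclass
class FrontalParams:
    fc1: float
    fc2: float
    fc3: float
    fc4: float
    fc4_signed: float
    fc5: float
    fc6: float
    fc7: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class SagittalParams:
    sc1: float
    sc2: float
    sc3: float
    sc4: float
    sc5: float
    sc6: float
    sc7: float
    sc8: float
    mt1: float
    mt2: float
    ml1: float
    ml2: float
    warnings: list[str] = field(default_factory=list)


def _row_canal_minimum(
    row: np.ndarray, lo: int, axis: float, refine: bool
) -> float | None:
    """Column of the local minimum closest to the symmetry axis within a
    band starting at absolute column ``lo``; ties towards smaller column.
    Optional three-point parabolic sub-pixel refinement."""
    n = row.size
    if n < 3 or row.max() <= 0 or np.ptp(row) == 0:
        return None
    interior = row[1:-1]
    # non-strict on both sides but strict on at least one, so plateau edges
    # count as minima while flat stretches do not
    is_min = (
        (interior <= row[:-2])
        & (interior <= row[2:])
        & ((interior < row[:-2]) | (interior < row[2:]))
    )
    idx = np.nonzero(is_min)[0] + 1
    if idx.size == 0:
        return None
    dist = np.abs(idx + lo - axis)
    best = idx[np.lexsort((idx, dist))[0]]
    col = float(best + lo)
    if refine:
        a, b, c = row[best - 1], row[best], row[best + 1]
        denom = a - 2 * b + c
        if denom > 0:
            col += float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return col


def extract_frontal_curve(
    roi: RoiImage,
    lm: LandmarkSet,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> FrontalCurve:
    values = roi.frame.values
    axis = lm.axis_col
    centre = roi.frame.n_cols // 2 - 1
    half = lm.delta_iz // 2
    lo, hi = centre - half, centre + half

    raw_rows, raw_cols = [], []
    for j in range(lm.jt, lm.jl + 1):
        col = _row_canal_minimum(values[j, lo : hi + 1], lo, axis, config.refine_canal_subpixel)
        if col is not None:
            raw_rows.append(j)
            raw_cols.append(col)
    if len(raw_rows) < 7:
        raise FitError(
            f"frontal curve underdetermined: {len(raw_rows)} canal minima for a degree-5 fit"
        )
    raw_rows = np.array(raw_rows)
    raw_cols = np.array(raw_cols)

    poly = Polynomial.fit(raw_rows, raw_cols, 5)
    rows = np.arange(lm.jt, lm.jl + 1)
    curve = poly(rows)
    lin = Polynomial.fit(rows, curve, 1).convert()
    intercept, slope = (list(lin.coef) + [0.0, 0.0])[:2]
    line = intercept + slope * rows
    return FrontalCurve(
        rows=rows,
        curve=curve,
        line=line,
        slope=float(slope),
        intercept=float(intercept),
        raw_rows=raw_rows,
        raw_minima=raw_cols,
        coeffs=poly.convert().coef,
    )


def frontal_params(fc: FrontalCurve, lm: LandmarkSet) -> FrontalParams:
    warnings_: list[str] = []
    rows, curve = fc.rows, fc.curve
    jt, jtl, jl = lm.jt, lm.jtl, lm.jl
    axis = lm.axis_col

    fc1 = float(np.abs(np.diff(curve)).sum())
    fc2 = float(np.var(curve, ddof=1))

    thoracic = curve[: jtl - jt + 1]  # rows jt..jtl inclusive
    lumbar = curve[jtl - jt :]  # rows jtl..jl inclusive (jtl in both, as printed)
    fc3 = float(thoracic.mean() / lumbar.mean())

    n_head = min(10, curve.size)
    if curve.size < 20:
        warnings_.append("region shorter than 10 rows; FC4 uses the full region")
        head = curve
        tail = curve
    else:
        head = curve[:n_head]
        tail = curve[-n_head:]
    fc4_signed = float((head.sum() - tail.sum()) / n_head)
    fc4 = abs(fc4_signed)

    fc5 = float(np.abs(curve - axis).max())
    fc6 = float(np.abs(curve - fc.line).sum())
    fc7 = abs(fc.slope)
    return FrontalParams(fc1, fc2, fc3, fc4, fc4_signed, fc5, fc6, fc7, warnings_)


def _interval_slope(z: np.ndarray, a: int, b: int) -> float:
    """Least-squares slope of z over rows [a, b] inclusive."""
    if b - a + 1 < 2:
        raise FitError(f"regression interval [{a}, {b}] too short")
    rows = np.arange(a, b + 1)
    return float(np.polyfit(rows, z[a : b + 1], 1)[0])


def _slope_angle(m1: float, m2: float, warnings_: list[str], label: str) -> float:
    denom = 1.0 + m1 * m2
    if denom == 0:
        warnings_.append(f"{label}: 1 + m1*m2 = 0; returning +/- pi/2 by continuity")
        return math.copysign(math.pi / 2, m1 - m2)
    return math.atan((m1 - m2) / denom)


def sagittal_params(lm: LandmarkSet) -> SagittalParams:
    warnings_: list[str] = []
    z = lm.z
    jt, jtmax, jtl, jlmin, jl = lm.jt, lm.jtmax, lm.jtl, lm.jlmin, lm.jl

    mt1 = _interval_slope(z, jt, jtmax)
    mt2 = _interval_slope(z, jtmax, jtl)
    ml1 = _interval_slope(z, jtl, jlmin)
    ml2 = _interval_slope(z, jlmin, jl)

    sc1 = _slope_angle(mt1, mt2, warnings_, "SC1")
    sc2 = _slope_angle(ml1, ml2, warnings_, "SC2")

    if z[jlmin] == 0 or lm.vz == 0:
        raise UndefinedRatioError("z(jlmin) or vz is zero")
    sc3 = float(z[jtmax] / z[jlmin])
    thor_sum = float(z[jt : jtl + 1].sum())
    lumb_sum = float(z[jtl : jl + 1].sum())
    sc4 = thor_sum / lumb_sum
    dth = jtl - jt + 1
    dlu = jl - jtl + 1
    sc5 = (thor_sum / dth) / (lumb_sum / dlu)
    sc6 = float((z[jtmax] - z[jlmin]) / (jtmax - jlmin))
    sc7 = float(z[jtmax] / lm.vz)
    sc8 = float(z[jlmin] / lm.vz)
    return SagittalParams(sc1, sc2, sc3, sc4, sc5, sc6, sc7, sc8, mt1, mt2, ml1, ml2, warnings_)
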
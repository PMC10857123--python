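"""Waist contour (W1-W4) and sacral/pelvic (P1-P4) parameters.

The waist contour is segmented per side with an adaptive threshold (mean
intensity of the lateral third of the extended lumbar span), smoothed by a
fourth-degree polynomial; the waist centre is the contour extremum closest
to the symmetry axis within the lumbar row span. A quadratic fit of the
same boundary points provides the curvature coefficients compared by W4.

The sacral imprint is the mean-thresholded ROI caudal of the lumbar end;
its per-side first/last segmented rows give the pelvic edges, its side
sums/means the symmetry ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DetectionError, FitError, UndefinedRatioError
from .landmarks import LandmarkSet
from .preprocess import RoiImage
from .thoracic_params import max_ratio


@dataclass
class WaistSide:
    rows: np.ndarray
    boundary: np.ndarray  # outermost supra-threshold column per row
    quartic: np.ndarray  # ascending coefficients of the fourth-degree fit
    quadratic: np.ndarray  # ascending coefficients of the second-degree fit
    jw: float  # waist centre row
    iw: float  # waist centre column
    aws: float  # quadratic curvature coefficient


@dataclass
class WaistResult:
    left: WaistSide
    right: WaistSide
    w0_vl: float
    w0_vr: float
    w0_hl: float
    w0_hr: float
    w1: float
    w1_signed: float
    w2: float
    w2_signed: float
    w3: float
    w3_signed: float
    w4: float
    w4_l: float
    w4_r: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class PelvicResult:
    jpu_l: int
    jpl_l: int
    jpu_r: int
    jpl_r: int
    p2: float
    p3: float
    p3_l: float
    p3_r: float
    p4: float
    p4_l: float
    p4_r: float
    warnings: list[str] = field(default_factory=list)


def _polynomial_extremum(coeffs: np.ndarray, lo: float, hi: float, maximise: bool) -> float:
    """Argument of the extremum of a polynomial (ascending coeffs) on
    [lo, hi], from the real critical points plus the interval endpoints."""
    poly = Polynomial(coeffs)
    candidates = [lo, hi]
    for root in poly.deriv().roots():
        if abs(root.imag) < 1e-9 and lo <= root.real <= hi:
            candidates.append(float(root.real))
    values = poly(np.array(candidates))
    idx = int(np.argmax(values)) if maximise else int(np.argmin(values))
    return float(candidates[idx])


def waist_params(
    roi: RoiImage, lm: LandmarkSet, config: PipelineConfig = DEFAULT_CONFIG
) -> WaistResult:
    warnings_: list[str] = []
    values = roi.frame.values
    axis = roi.axis_col
    n_rows, n_cols = values.shape
    r0 = max(0, lm.jtl - 10)
    r1 = min(n_rows - 1, lm.jl + 10)
    rows = np.arange(r0, r1 + 1)
    third = n_cols // 3
    left_cols = slice(0, third)
    right_cols = slice(n_cols - third, n_cols)
    left_half = slice(0, int(math.floor(axis)) + 1)
    right_half = slice(int(math.ceil(axis)), n_cols)

    sides = {}
    for name, lat_cols, half, outermost in (
        ("left", left_cols, left_half, "min"),
        ("right", right_cols, right_half, "max"),
    ):
        region = values[r0 : r1 + 1, lat_cols]
        positive = region[region > 0]
        if positive.size == 0:
            raise DetectionError(f"{name} waist imprint empty")
        threshold = float(positive.mean())

        brows, bcols = [], []
        for j in rows:
            row = values[j, half]
            above = np.nonzero(row > threshold)[0]
            if above.size == 0:
                continue
            col = above[0] if outermost == "min" else above[-1]
            brows.append(j)
            bcols.append(col + half.start)
        if len(brows) < 5:
            raise FitError(f"{name} waist boundary underdetermined ({len(brows)} rows)")
        brows = np.array(brows, dtype=float)
        bcols = np.array(bcols, dtype=float)

        quartic = Polynomial.fit(brows, bcols, 4).convert().coef
        quadratic = Polynomial.fit(brows, bcols, 2).convert().coef
        aws = float(quadratic[2]) if quadratic.size > 2 else 0.0
        # most medial excursion of the fitted contour inside the lumbar span:
        # a maximum of the left boundary column, a minimum of the right
        jw = _polynomial_extremum(quartic, lm.jtl, lm.jl, maximise=(name == "left"))
        iw = float(Polynomial(quartic)(jw))
        sides[name] = WaistSide(
            rows=brows, boundary=bcols, quartic=quartic, quadratic=quadratic,
            jw=jw, iw=iw, aws=aws,
        )

    left, right = sides["left"], sides["right"]
    w1_signed = left.jw - right.jw
    hl = axis - left.iw
    hr = right.iw - axis
    w2_signed = hl - hr
    if left.iw == right.iw:
        w3_signed = 90.0 if left.jw != right.jw else 0.0
        warnings_.append("waist centres share a column; W3 set by continuity")
    else:
        w3_signed = math.degrees(math.atan((left.jw - right.jw) / (left.iw - right.iw)))
    al, ar = abs(left.aws), abs(right.aws)
    if al == 0 or ar == 0:
        raise UndefinedRatioError("zero waist curvature coefficient")
    return WaistResult(
        left=left,
        right=right,
        w0_vl=left.jw,
        w0_vr=right.jw,
        w0_hl=hl,
        w0_hr=hr,
        w1=abs(w1_signed),
        w1_signed=w1_signed,
        w2=abs(w2_signed),
        w2_signed=w2_signed,
        w3=abs(w3_signed),
        w3_signed=w3_signed,
        w4=max(al / ar, ar / al),
        w4_l=al,
        w4_r=ar,
        warnings=warnings_,
    )


def sacral_slope(lm: LandmarkSet) -> float:
    """P1: least-squares slope of z over [jl, jsmax]."""
    if lm.jsmax - lm.jl + 1 < 2:
        raise FitError("sacral slope interval shorter than two rows")
    rows = np.arange(lm.jl, lm.jsmax + 1)
    return float(np.polyfit(rows, lm.z[lm.jl : lm.jsmax + 1], 1)[0])


def pelvic_params(
    roi: RoiImage, lm: LandmarkSet, config: PipelineConfig = DEFAULT_CONFIG
) -> PelvicResult:
    values = roi.frame.values
    mask = roi.mask
    axis = roi.axis_col
    n_rows, n_cols = values.shape
    rows = slice(lm.jl, n_rows)
    region = values[rows]
    inside = region[mask[rows]]
    if inside.size == 0:
        raise DetectionError("sacral region carries no ROI pixels")
    threshold = float(inside.mean())
    segmented = region > threshold

    left_half = slice(0, int(math.floor(axis)) + 1)
    right_half = slice(int(math.ceil(axis)), n_cols)
    sides = {}
    for name, half in (("left", left_half), ("right", right_half)):
        seg = segmented[:, half]
        filled = np.nonzero(seg.any(axis=1))[0]
        if filled.size == 0:
            raise DetectionError(f"empty {name} sacral segment")
        jpu = lm.jl + int(filled[0])
        jpl = lm.jl + int(filled[-1])
        vals = region[:, half][seg]
        sides[name] = (jpu, jpl, float(vals.sum()), float(vals.mean()))

    (jpu_l, jpl_l, sum_l, mean_l) = sides["left"]
    (jpu_r, jpl_r, sum_r, mean_r) = sides["right"]
    p2 = abs(jpu_l - jpu_r) + abs(jpl_l - jpl_r)
    return PelvicResult(
        jpu_l=jpu_l,
        jpl_l=jpl_l,
        jpu_r=jpu_r,
        jpl_r=jpl_r,
        p2=float(p2),
        p3=max_ratio(sum_l, sum_r),
        p3_l=sum_l,
        p3_r=sum_r,
        p4=max_ratio(mean_l, mean_r),
        p4_l=mean_l,
        p4_r=mean_r,
        warnings=[],
    )
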
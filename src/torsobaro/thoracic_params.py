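"""Shoulder contour (S), scapula (SB) and torso-symmetry (TS) parameters.

Left/right splits use the continuous mirror axis between the two central
columns, so that the two half-sets are exact mirror images and every ratio
parameter equals 1 on a mirror-symmetric imprint. Max-ratio parameters are
max(x/y, y/x) and therefore >= 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DetectionError, UndefinedRatioError
from .landmarks import LandmarkSet
from .preprocess import RoiImage
from .pressure_io import PressureFrame


@dataclass
class ShoulderResult:
    js_l: int
    js_r: int
    ms_l: float
    ms_r: float
    s1: float
    s1_signed: float
    s2: float
    s2_l: float
    s2_r: float
    contour_l: tuple[np.ndarray, np.ndarray]  # (columns, first supra-threshold rows)
    contour_r: tuple[np.ndarray, np.ndarray]
    warnings: list[str] = field(default_factory=list)


@dataclass
class ScapulaCentres:
    jsb_l: int
    isb_l: int
    jsb_r: int
    isb_r: int


@dataclass
class ScapulaResult:
    centres: ScapulaCentres
    sb0_vl: int
    sb0_vr: int
    sb0_hl: float
    sb0_hr: float
    sb1: float
    sb1_signed: float
    sb2: float
    sb2_signed: float
    sb3: float
    sb3_signed: float
    sb4: float
    sb4_l: float
    sb4_r: float
    sb5: float
    sb5_l: float
    sb5_r: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class TorsoSymmetryResult:
    lcop_rows: np.ndarray
    lcop: np.ndarray
    ts1: float
    ts1_signed: float
    ts2: float
    ts2_l: float
    ts2_r: float
    ts3: float
    ts3_l: float
    ts3_r: float
    ts4: float
    ts4_l: float
    ts4_r: float
    ts5: float
    warnings: list[str] = field(default_factory=list)


def max_ratio(a: float, b: float) -> float:
    if a <= 0 or b <= 0:
        raise UndefinedRatioError(f"non-positive side values ({a}, {b})")
    return max(a / b, b / a)


def _first_crossing_contour(region: np.ndarray, threshold: float):
    """Per column, the first supra-threshold row (top-down); columns without
    one are dropped."""
    above = region > threshold
    has = above.any(axis=0)
    cols = np.nonzero(has)[0]
    rows = above[:, cols].argmax(axis=0)
    return cols, rows


def shoulder_params(
    roi: RoiImage, lm: LandmarkSet, config: PipelineConfig = DEFAULT_CONFIG
) -> ShoulderResult:
    """Shoulder edges and contour slopes from the left/right thirds of the
    upper third of the segment spanning [jts, jsmax] x [il-10, ir+10]; each
    side region is thresholded at its own mean."""
    warnings_: list[str] = []
    values = roi.frame.values
    n_cols = values.shape[1]
    r0, r1 = lm.jts, lm.jsmax
    c0 = max(0, lm.il - 10)
    c1 = min(n_cols - 1, lm.ir + 10)
    height = r1 - r0 + 1
    width = c1 - c0 + 1
    upper = slice(r0, r0 + max(1, height // 3))
    third = max(1, width // 3)

    sides = {}
    for name, cols in (("left", slice(c0, c0 + third)), ("right", slice(c1 + 1 - third, c1 + 1))):
        region = values[upper, cols]
        threshold = float(region.mean())
        ccols, crows = _first_crossing_contour(region, threshold)
        if ccols.size == 0:
            raise DetectionError(f"{name} shoulder region empty after thresholding")
        abs_cols = ccols + cols.start
        abs_rows = crows + r0
        js = int(abs_rows.min())
        if ccols.size >= 2:
            ms = float(np.polyfit(abs_cols, abs_rows, 1)[0])
        else:
            ms = 0.0
            warnings_.append(f"{name} shoulder contour has a single column; slope set to 0")
        sides[name] = (js, ms, (abs_cols, abs_rows))

    js_l, ms_l, contour_l = sides["left"]
    js_r, ms_r, contour_r = sides["right"]
    s1_signed = float(js_l - js_r)
    # Contour slopes mirror in sign between the sides; their magnitudes are
    # compared so that a symmetric imprint yields exactly 1.
    al, ar = abs(ms_l), abs(ms_r)
    if al == 0 and ar == 0:
        warnings_.append("both shoulder slopes are zero; S2 set to 1")
        s2 = 1.0
    elif al == 0 or ar == 0:
        warnings_.append("one shoulder slope is zero; S2 is infinite")
        s2 = math.inf
    else:
        s2 = max(al / ar, ar / al)
    return ShoulderResult(
        js_l=js_l,
        js_r=js_r,
        ms_l=ms_l,
        ms_r=ms_r,
        s1=abs(s1_signed),
        s1_signed=s1_signed,
        s2=s2,
        s2_l=al,
        s2_r=ar,
        contour_l=contour_l,
        contour_r=contour_r,
        warnings=warnings_,
    )


def _side_maxima(region: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hi = ndimage.maximum_filter(region, size=3, mode="nearest")
    lo = ndimage.minimum_filter(region, size=3, mode="nearest")
    # neighbourhood maximum that actually rises above its surroundings, so
    # flat plateaus and image borders do not spawn spurious candidates
    cand = (region == hi) & (region > lo) & (region > 0)
    coords = np.argwhere(cand)
    return coords, region[cand]


def locate_scapulae(
    Is: PressureFrame, lm: LandmarkSet, config: PipelineConfig = DEFAULT_CONFIG
) -> ScapulaCentres:
    """Scapula centres from the lightly filtered image: per side interval,
    presegment at tv, smooth (3x3 Gaussian, sigma 2), take the two highest
    local maxima and pick the more lateral one; at equal lateral offset the
    higher intensity wins."""
    values = Is.values
    axis = Is.axis_col
    n_cols = Is.n_cols
    quarter = (lm.ir - lm.il) / 4.0
    rows = slice(lm.jt, lm.jtl + 1)
    regions = {
        "left": slice(0, int(math.floor(axis - quarter)) + 1),
        "right": slice(int(math.ceil(axis + quarter)), n_cols),
    }
    centres = {}
    for name, cols in regions.items():
        sub = values[rows, cols].copy()
        sub[sub < config.tv] = 0.0
        sub = ndimage.gaussian_filter(sub, sigma=2, radius=1, mode="nearest")
        coords, heights = _side_maxima(sub)
        if coords.shape[0] == 0:
            raise DetectionError(f"no local maximum in the {name} scapula interval")
        order = np.argsort(-heights, kind="stable")[:2]
        cand = coords[order]
        abs_i = cand[:, 1] + cols.start
        lateral = np.abs(abs_i - axis)
        # lexicographic: most lateral first, intensity decides exact ties
        pick = int(np.lexsort((-heights[order], -lateral))[0])
        centres[name] = (int(cand[pick, 0] + rows.start), int(abs_i[pick]))
    (jl_, il_), (jr_, ir_) = centres["left"], centres["right"]
    return ScapulaCentres(jsb_l=jl_, isb_l=il_, jsb_r=jr_, isb_r=ir_)


def scapula_params(
    Is: PressureFrame, centres: ScapulaCentres, window: int = 11
) -> ScapulaResult:
    """Position and intensity symmetry of 11x11 windows at the centres."""
    warnings_: list[str] = []
    values = Is.values
    axis = Is.axis_col
    half = window // 2

    def window_of(j: int, i: int) -> np.ndarray:
        j0, j1 = j - half, j + half + 1
        i0, i1 = i - half, i + half + 1
        if j0 < 0 or i0 < 0 or j1 > values.shape[0] or i1 > values.shape[1]:
            warnings_.append(f"scapula window at ({j}, {i}) clipped to the image")
            j0, i0 = max(0, j0), max(0, i0)
            j1, i1 = min(values.shape[0], j1), min(values.shape[1], i1)
        return values[j0:j1, i0:i1]

    win_l = window_of(centres.jsb_l, centres.isb_l)
    win_r = window_of(centres.jsb_r, centres.isb_r)
    sb4_l, sb4_r = float(win_l.max()), float(win_r.max())
    sb5_l, sb5_r = float(win_l.mean()), float(win_r.mean())

    sb1_signed = float(centres.jsb_l - centres.jsb_r)
    hl = float(axis - centres.isb_l)
    hr = float(centres.isb_r - axis)
    sb2_signed = hl - hr
    sb3_signed = math.degrees(
        math.atan((centres.jsb_r - centres.jsb_l) / (centres.isb_r - centres.isb_l))
    )
    return ScapulaResult(
        centres=centres,
        sb0_vl=centres.jsb_l,
        sb0_vr=centres.jsb_r,
        sb0_hl=hl,
        sb0_hr=hr,
        sb1=abs(sb1_signed),
        sb1_signed=sb1_signed,
        sb2=abs(sb2_signed),
        sb2_signed=sb2_signed,
        sb3=abs(sb3_signed),
        sb3_signed=sb3_signed,
        sb4=max_ratio(sb4_l, sb4_r),
        sb4_l=sb4_l,
        sb4_r=sb4_r,
        sb5=max_ratio(sb5_l, sb5_r),
        sb5_l=sb5_l,
        sb5_r=sb5_r,
        warnings=warnings_,
    )


def _masked_side(values, mask, rows: slice, cols: slice):
    sub = values[rows, cols]
    sel = mask[rows, cols]
    return sub[sel]


def torso_symmetry_params(
    roi: RoiImage,
    lm: LandmarkSet,
    centres: ScapulaCentres,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> TorsoSymmetryResult:
    warnings_: list[str] = []
    values = roi.frame.values
    mask = roi.mask
    axis = roi.axis_col
    n_rows, n_cols = values.shape
    left_end = int(math.floor(axis)) + 1  # columns strictly left of the axis
    right_start = int(math.ceil(axis))

    # centre of pressure curve over the torso width
    start_row = lm.jts if config.ts1_start == "jts" else lm.jt
    cop_rows, cop_vals = [], []
    cols = np.arange(lm.il, lm.ir + 1)
    for j in range(start_row, lm.jl + 1):
        row = values[j, lm.il : lm.ir + 1]
        total = row.sum()
        if total <= 0:
            warnings_.append(f"row {j} carries no pressure; skipped in Lcop")
            continue
        cop_rows.append(j)
        cop_vals.append(float((cols * row).sum() / total))
    lcop = np.array(cop_vals)
    deviations = lcop - axis
    ts1 = float(np.abs(deviations).sum())
    ts1_signed = float(deviations.sum())

    # thoracic segments, rows [jts, jlmin], split at the axis with 10 px margins
    t_rows = slice(lm.jts, lm.jlmin + 1)
    t_left = _masked_side(values, mask, t_rows, slice(max(0, lm.il - 10), left_end))
    t_right = _masked_side(values, mask, t_rows, slice(right_start, min(n_cols, lm.ir + 10 + 1)))

    # combined thoracolumbar segments, from each side's scapula row + 10
    half_width = (lm.ir - lm.il) / 2.0
    tl_left = _masked_side(
        values,
        mask,
        slice(centres.jsb_l + 10, lm.jl + 1),
        slice(max(0, int(math.ceil(axis - half_width))), left_end),
    )
    tl_right = _masked_side(
        values,
        mask,
        slice(centres.jsb_r + 10, lm.jl + 1),
        slice(right_start, min(n_cols, int(math.floor(axis + half_width)) + 1)),
    )
    for name, side in (("thoracic", (t_left, t_right)), ("thoracolumbar", (tl_left, tl_right))):
        if side[0].size == 0 or side[1].size == 0:
            raise DetectionError(f"empty {name} side segment")

    ts2_l, ts2_r = float(tl_left.mean()), float(tl_right.mean())
    ts3_l, ts3_r = float(tl_left.max()), float(tl_right.max())
    ts4_l, ts4_r = float(t_left.sum()), float(t_right.sum())

    # mirrored percentage deviation of the mean-thresholded imprint
    inside = values[mask]
    thr = float(inside.mean()) if inside.size else 0.0
    seg = np.where(values > thr, values, 0.0)
    seg_mirror = seg[:, ::-1]
    band = slice(lm.jts, lm.jlmin + 1)
    overlap = (seg[band] > 0) & (seg_mirror[band] > 0)
    if not overlap.any():
        raise UndefinedRatioError("empty overlap set for the mirrored comparison")
    ratio = seg[band][overlap] / seg_mirror[band][overlap]
    ts5 = float(np.abs(1.0 - ratio).mean() * 100.0)

    return TorsoSymmetryResult(
        lcop_rows=np.array(cop_rows),
        lcop=lcop,
        ts1=ts1,
        ts1_signed=ts1_signed,
        ts2=max_ratio(ts2_l, ts2_r),
        ts2_l=ts2_l,
        ts2_r=ts2_r,
        ts3=max_ratio(ts3_l, ts3_r),
        ts3_l=ts3_l,
        ts3_r=ts3_r,
        ts4=max_ratio(ts4_l, ts4_r),
        ts4_l=ts4_l,
        ts4_r=ts4_r,
        ts5=ts5,
        warnings=warnings_,
    )
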
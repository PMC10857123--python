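"""Longitudinal landmark detection, lateral reference positions and
reference distances.

All rows/columns are 0-based internally. The sagittal profile z(j) is the
mean over a central band of ``delta_iz + 1`` columns of the aligned smooth
image. Landmarks:

* jts     first row whose ROI row-sum exceeds the threshold tv
* jtmax   thoracic maximum of z
* jlmin   lumbar minimum of z (trough between the two lobes)
* jsmax   sacral maximum of z
* jt/jtl/jl  crossings of z with the reference value vz (mean of z over
  [jts, jlmin])
* il/ir   columns of maximum concave curvature on the left/right ROI
  contour (the waist notches)

Distances use the inclusive pixel convention d = end - start + 1, the only
convention consistent with the published grand means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import DetectionError
from .preprocess import AlignedImages, RoiImage
from .pressure_io import PressureFrame


@dataclass
class LandmarkSet:
    jts: int
    jt: int
    jtmax: int
    jtl: int
    jlmin: int
    jl: int
    jsmax: int
    il: int
    ir: int
    z: np.ndarray
    vz: float
    tv: float
    delta_iz: int
    axis_col: float
    pixel_mm: float
    n_rows: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = (self.jts, self.jt, self.jtmax, self.jtl, self.jlmin, self.jl, self.jsmax)
        names = ("jts", "jt", "jtmax", "jtl", "jlmin", "jl", "jsmax")
        if not (self.jts <= self.jt < self.jtmax < self.jtl < self.jlmin < self.jl <= self.jsmax):
            pairs = ", ".join(f"{n}={v}" for n, v in zip(names, order))
            raise DetectionError(f"landmark ordering violated: {pairs}")
        if not (self.il < self.axis_col < self.ir):
            raise DetectionError(
                f"reference positions do not straddle the axis: il={self.il}, ir={self.ir}"
            )


@dataclass
class ReferenceDistances:
    dl: float
    dw: float
    dth: float
    dlu: float
    ds: float
    pixel_mm: float

    def as_mm(self) -> dict[str, float]:
        return {k: getattr(self, k) * self.pixel_mm for k in ("dl", "dw", "dth", "dlu", "ds")}


def inclusive_distance(start: float, end: float) -> float:
    """Inclusive pixel distance between two landmark coordinates."""
    return end - start + 1


def px_to_mm(px: float, pixel_mm: float = 5.1) -> float:
    return px * pixel_mm


def detect_torso_start(roi: RoiImage, tv: float) -> int:
    """Smallest row whose ROI row-sum exceeds tv."""
    row_sums = roi.frame.values.sum(axis=1)
    hits = np.nonzero(row_sums > tv)[0]
    if hits.size == 0:
        raise DetectionError(f"torso not found: no row-sum exceeds tv={tv}")
    return int(hits[0])


def mean_intensity_curve(I: PressureFrame, delta_iz: int = 30) -> np.ndarray:
    """Per-row average over the central band of delta_iz + 1 columns of the
    aligned image (not the ROI)."""
    if delta_iz % 2 != 0:
        raise ValueError("delta_iz must be even")
    centre = I.n_cols // 2 - 1
    half = delta_iz // 2
    lo, hi = centre - half, centre + half
    if lo < 0 or hi >= I.n_cols:
        raise ValueError("central band exceeds image width")
    return I.values[:, lo : hi + 1].mean(axis=1)


def detect_profile_extrema(z: np.ndarray, jts: int) -> tuple[int, int, int]:
    """(jtmax, jlmin, jsmax): the two highest interior peaks of z caudal of
    jts bracket the trough. Ties break towards smaller j (plateau left edge,
    stable peak ranking, first minimum)."""
    zz = np.asarray(z, dtype=float)[jts:]
    peaks, props = signal.find_peaks(zz, plateau_size=1)
    pos = props["left_edges"]
    if pos.size < 2:
        raise DetectionError(
            "profile extrema not found: fewer than two interior maxima in z "
            f"({pos.size} detected)"
        )
    order = np.argsort(-zz[pos], kind="stable")
    top2 = np.sort(pos[order[:2]])
    jtmax = int(top2[0]) + jts
    jsmax = int(top2[1]) + jts
    jlmin = jtmax + int(np.argmin(z[jtmax : jsmax + 1]))
    if not (jtmax < jlmin < jsmax):
        raise DetectionError("lumbar minimum not interior to the two maxima")
    return jtmax, jlmin, jsmax


def region_boundaries(
    z: np.ndarray, jts: int, jtmax: int, jlmin: int, jsmax: int
) -> tuple[float, int, int, int]:
    """(vz, jt, jtl, jl): crossings of z with vz, localised at the first row
    on the crossing's far side."""
    z = np.asarray(z, dtype=float)
    if np.ptp(z[jts : jsmax + 1]) == 0:
        raise DetectionError("degenerate profile: z is constant, no crossings exist")
    vz = float(z[jts : jlmin + 1].mean())

    above = z[jts : jtmax + 1] >= vz
    if not above.any():
        raise DetectionError("thoracic start jt not found: z never reaches vz")
    jt = jts + int(np.argmax(above))

    below = z[jtmax + 1 : jlmin + 1] <= vz
    if not below.any():
        raise DetectionError("thoracolumbar transition jtl not found: z never falls to vz")
    jtl = jtmax + 1 + int(np.argmax(below))

    above2 = z[jlmin + 1 : jsmax + 1] >= vz
    if not above2.any():
        raise DetectionError("lumbar end jl not found: z never recovers to vz")
    jl = jlmin + 1 + int(np.argmax(above2))
    return vz, jt, jtl, jl


def _side_contours(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rows with mask support and the left/right boundary column per row."""
    rows = np.nonzero(mask.any(axis=1))[0]
    left = mask[rows].argmax(axis=1)
    right = mask.shape[1] - 1 - mask[rows, ::-1].argmax(axis=1)
    return rows, left, right


def reference_positions(
    roi: RoiImage, config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[int, int]:
    """Columns of maximum concave curvature on each side contour of the ROI
    mask (discrete second difference over a +/- curvature_window row arc on
    the lightly smoothed contour)."""
    w = config.curvature_window
    rows, left, right = _side_contours(roi.mask)
    if rows.size < 2 * w + 1:
        raise DetectionError("ROI contour shorter than the curvature window")
    left_s = ndimage.uniform_filter1d(left.astype(float), size=3, mode="nearest")
    right_s = ndimage.uniform_filter1d(right.astype(float), size=3, mode="nearest")

    # Concave-inward curvature: the waist notch is a local maximum of the
    # left boundary column and a local minimum of the right boundary column.
    curv_left = 2 * left_s[w:-w] - left_s[: -2 * w] - left_s[2 * w :]
    curv_right = right_s[: -2 * w] + right_s[2 * w :] - 2 * right_s[w:-w]

    if curv_left.max() <= 0 or curv_right.max() <= 0:
        raise DetectionError("no concave curvature on the ROI contour")
    il = int(left[w + int(np.argmax(curv_left))])
    ir = int(right[w + int(np.argmax(curv_right))])
    return il, ir


def reference_distances(lm: LandmarkSet) -> ReferenceDistances:
    return ReferenceDistances(
        dl=inclusive_distance(lm.jts, lm.jsmax),
        dw=inclusive_distance(lm.il, lm.ir),
        dth=inclusive_distance(lm.jt, lm.jtl),
        dlu=inclusive_distance(lm.jtl, lm.jl),
        ds=inclusive_distance(lm.jl, lm.n_rows - 1),
        pixel_mm=lm.pixel_mm,
    )


def detect_landmarks(
    aligned: AlignedImages,
    roi: RoiImage,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> LandmarkSet:
    """Run the full landmark chain on an aligned image and its ROI."""
    jts = detect_torso_start(roi, config.tv)
    z = mean_intensity_curve(aligned.I, config.delta_iz)
    jtmax, jlmin, jsmax = detect_profile_extrema(z, jts)
    vz, jt, jtl, jl = region_boundaries(z, jts, jtmax, jlmin, jsmax)
    il, ir = reference_positions(roi, config)
    return LandmarkSet(
        jts=jts,
        jt=jt,
        jtmax=jtmax,
        jtl=jtl,
        jlmin=jlmin,
        jl=jl,
        jsmax=jsmax,
        il=il,
        ir=ir,
        z=z,
        vz=vz,
        tv=config.tv,
        delta_iz=config.delta_iz,
        axis_col=aligned.I.axis_col,
        pixel_mm=aligned.I.pixel_mm,
        n_rows=aligned.I.n_rows,
    )
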
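"""Filtering, mirror-symmetry alignment and ROI mask fitting.

The alignment searches an integer grid of rotations and horizontal
translations for the transform that minimises the sum of absolute
differences (SAD) between the transformed image and the mirrored rotated
image. Because matching an imprint to its own mirror doubles the offset of
the imprint axis from the image centre, the optimal translation ``t*`` is
halved to obtain the centring translation ``tc``. Afterwards the caudal
edge of the imprint is shifted onto the last row.

The ROI is obtained by scaling a parametric torso-shaped template mask
(rectangular trunk, elliptic shoulder caps, concave waist insets) anchored
at the bottom row and the symmetry axis, minimising a two-region
inside/outside absolute-deviation energy over a coarse-to-fine scale grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import AlignmentError, DomainError, FitError
from .pressure_io import PressureFrame

# Template geometry, expressed relative to the frame size so non-default
# grids scale consistently. Fractions were chosen to cover an imprint that
# spans ~80% of the rows and ~56% of the columns at unit scale.
TEMPLATE_HEIGHT_FRAC = 0.8
TEMPLATE_HALF_WIDTH_FRAC = 0.28
TEMPLATE_CAP_FRAC = 0.08
TEMPLATE_WAIST_Y = 0.47
TEMPLATE_WAIST_SIGMA = 0.09
TEMPLATE_WAIST_DEPTH = 0.18


@dataclass
class AlignedImages:
    """Smooth image I and lightly filtered image Is after the shared
    derotation/centring transform."""

    I: PressureFrame
    Is: PressureFrame
    alpha_deg: int
    tc_px: int
    bottom_shift_px: int


@dataclass
class RoiImage:
    """Masked aligned image with the fitted template scales."""

    frame: PressureFrame  # I * mask
    mask: np.ndarray  # boolean
    sj: float
    si: float

    @property
    def axis_col(self) -> float:
        return self.frame.axis_col


def filter_frames(frame: PressureFrame) -> tuple[PressureFrame, PressureFrame]:
    """Return (I, Is): median 15x5 then 3x3 sigma-3 Gaussian; median 5x1.

    Kernel dimensions are (rows x cols); borders replicate the edge value.
    """
    a = frame.values
    smooth = ndimage.median_filter(a, size=(15, 5), mode="nearest")
    smooth = ndimage.gaussian_filter(smooth, sigma=3, radius=1, mode="nearest")
    light = ndimage.median_filter(a, size=(5, 1), mode="nearest")
    return frame.copy(values=smooth), frame.copy(values=light)


def _rotate(values: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Bilinear rotation about the image centre with zero fill; negative
    interpolation overshoot is clipped (pressure cannot be negative)."""
    if alpha_deg == 0:
        return values
    out = ndimage.rotate(values, alpha_deg, reshape=False, order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, None)


def _shift_cols(values: np.ndarray, t: int) -> np.ndarray:
    """Shift columns by t (positive towards larger i), zero fill."""
    if t == 0:
        return values
    out = np.zeros_like(values)
    if t > 0:
        out[:, t:] = values[:, :-t]
    else:
        out[:, :t] = values[:, -t:]
    return out


def _shift_rows(values: np.ndarray, s: int) -> np.ndarray:
    """Shift rows by s (positive towards larger j / caudal), zero fill."""
    if s == 0:
        return values
    out = np.zeros_like(values)
    if s > 0:
        out[s:, :] = values[:-s, :]
    else:
        out[:s, :] = values[-s:, :]
    return out


def symmetry_cost(
    frame: PressureFrame,
    alpha_deg: int,
    t_px: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> float:
    """SAD between the rotated+translated image and the mirrored rotated
    image; out-of-bounds pixels read as zero."""
    if abs(alpha_deg) > config.alpha_range:
        raise DomainError(f"|alpha| = {abs(alpha_deg)} exceeds {config.alpha_range}")
    if abs(t_px) > config.t_range:
        raise DomainError(f"|t| = {abs(t_px)} exceeds {config.t_range}")
    rot = _rotate(frame.values, alpha_deg)
    return float(np.abs(_shift_cols(rot, t_px) - rot[:, ::-1]).sum())


def align(
    I: PressureFrame,
    Is: PressureFrame,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> AlignedImages:
    """Exhaustive integer grid search minimising the symmetry cost of I,
    then apply rotation and the halved translation to both images and
    anchor the caudal imprint edge at the last row."""
    a = I.values
    if not a.any():
        raise AlignmentError("image carries no imprint (all zero)")
    best: tuple[float, int, int] | None = None
    for alpha in range(-config.alpha_range, config.alpha_range + 1):
        rot = _rotate(a, alpha)
        mirror = rot[:, ::-1]
        for t in range(-config.t_range, config.t_range + 1):
            cost = float(np.abs(_shift_cols(rot, t) - mirror).sum())
            if best is None or cost < best[0]:
                best = (cost, alpha, t)
    _, alpha, t_star = best
    tc = int(round(t_star / 2))

    out_i = _shift_cols(_rotate(a, alpha), tc)
    out_s = _shift_cols(_rotate(Is.values, alpha), tc)

    row_sums = out_i.sum(axis=1)
    filled = np.nonzero(row_sums > config.tv_bottom)[0]
    if filled.size == 0:
        raise AlignmentError("no row exceeds the bottom-edge threshold")
    shift = (a.shape[0] - 1) - int(filled[-1])
    out_i = _shift_rows(out_i, shift)
    out_s = _shift_rows(out_s, shift)
    return AlignedImages(
        I=I.copy(values=out_i),
        Is=Is.copy(values=out_s),
        alpha_deg=int(alpha),
        tc_px=tc,
        bottom_shift_px=shift,
    )


def template_mask(
    sj: float,
    si: float,
    shape: tuple[int, int] = (160, 100),
) -> np.ndarray:
    """Torso-shaped binary stencil scaled by (sj, si), anchored at the
    bottom row and centred on the column mirror axis.

    The half-width profile over normalised depth y (0 = cranial edge) is an
    elliptic shoulder cap ramp followed by a full-width trunk carrying a
    Gaussian waist inset.
    """
    n_rows, n_cols = shape
    axis = (n_cols - 1) / 2.0
    height = int(round(TEMPLATE_HEIGHT_FRAC * n_rows * sj))
    height = max(2, min(height, n_rows))
    top = n_rows - height
    rows = np.arange(top, n_rows)
    y = (rows - top) / height

    w = np.ones_like(y)
    cap = y < TEMPLATE_CAP_FRAC
    w[cap] = np.sqrt(np.clip(1.0 - ((TEMPLATE_CAP_FRAC - y[cap]) / TEMPLATE_CAP_FRAC) ** 2, 0.0, 1.0))
    w = w * (1.0 - TEMPLATE_WAIST_DEPTH * np.exp(-(((y - TEMPLATE_WAIST_Y) / TEMPLATE_WAIST_SIGMA) ** 2)))
    half_width = TEMPLATE_HALF_WIDTH_FRAC * n_cols * si * w

    mask = np.zeros(shape, dtype=bool)
    cols = np.arange(n_cols)
    mask[top:, :] = np.abs(cols[None, :] - axis) <= half_width[:, None]
    return mask


def roi_energy(values: np.ndarray, mask: np.ndarray) -> float:
    """Two-region energy: sum of absolute deviations from the inside mean
    plus the same outside the mask."""
    inside = values[mask]
    outside = values[~mask]
    e = 0.0
    if inside.size:
        e += float(np.abs(inside - inside.mean()).sum())
    if outside.size:
        e += float(np.abs(outside - outside.mean()).sum())
    return e


def _scale_axis(config: PipelineConfig, step: float) -> np.ndarray:
    n = int(round((config.scale_max - config.scale_min) / step))
    return config.scale_min + step * np.arange(n + 1)


def fit_roi(I: PressureFrame, config: PipelineConfig = DEFAULT_CONFIG) -> RoiImage:
    """Fit the template scales coarse-to-fine and return the masked image.

    The coarse pass scans the full grid at ``scale_coarse_step``; the fine
    pass refines around the coarse optimum at ``scale_step``. A degenerate
    energy landscape (constant image) yields the smallest admissible mask
    with a warning.
    """
    a = I.values
    shape = a.shape

    def scan(sj_grid: np.ndarray, si_grid: np.ndarray):
        best = None
        energies = []
        for sj in sj_grid:
            for si in si_grid:
                e = roi_energy(a, template_mask(sj, si, shape))
                energies.append(e)
                if best is None or e < best[0] - 1e-12:
                    best = (e, float(sj), float(si))
        return best, energies

    coarse = _scale_axis(config, config.scale_coarse_step)
    (e0, sj0, si0), energies = scan(coarse, coarse)
    if max(energies) - min(energies) <= 1e-9 * max(1.0, max(energies)):
        warnings.warn("degenerate ROI energy landscape; returning smallest mask")
        sj, si = config.scale_min, config.scale_min
        return RoiImage(
            frame=I.copy(values=a * template_mask(sj, si, shape)),
            mask=template_mask(sj, si, shape),
            sj=sj,
            si=si,
        )

    def refine_axis(centre: float) -> np.ndarray:
        lo = max(config.scale_min, centre - config.scale_coarse_step)
        hi = min(config.scale_max, centre + config.scale_coarse_step)
        n = int(round((hi - lo) / config.scale_step))
        return lo + config.scale_step * np.arange(n + 1)

    (e1, sj1, si1), _ = scan(refine_axis(sj0), refine_axis(si0))
    if e1 > e0:  # pragma: no cover - coarse point is inside the fine grid
        raise FitError("refinement worsened the ROI energy")
    mask = template_mask(sj1, si1, shape)
    return RoiImage(frame=I.copy(values=a * mask), mask=mask, sj=sj1, si=si1)
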
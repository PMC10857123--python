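"""Parametric torso pressure phantoms and repeated-measurement studies.

A phantom superposes smooth anisotropic Gaussian bumps (thoracic bulk,
scapulae, sacral/gluteal blobs) on a torso-shaped support with rounded
shoulder caps, per-side waist concavities and a carved midline canal, then
applies placement rotation/translation, sensor noise and optional thin
fold-artifact lines. Every recoverable quantity (landmark rows, canal
path, injected asymmetries, placement) is returned as ground truth.

Intensities are on the raw-sensor scale the pipeline defaults assume
(imprint values of order 1e4, so row sums dwarf the tv = 7000 threshold).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml
from scipy import ndimage

from .errors import SpecError
from .pressure_io import (
    DEFAULT_PIXEL_MM,
    DEFAULT_SAMPLE_RATE_HZ,
    PressureFrame,
    Recording,
)


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (160, 100)
    pixel_mm: float = DEFAULT_PIXEL_MM

    # support geometry (px)
    torso_length: float = 128.0
    half_width: float = 26.0
    cap_rows: float = 8.0
    edge_taper: float = 1.5

    # baseline and sagittal structure (prv)
    base: float = 6000.0
    thoracic_amp: float = 5000.0
    thoracic_row: float = 50.0
    thoracic_sigma: float = 13.0
    thoracic_lat_sigma: float = 22.0
    # broad lordosis trough so the lumbar minimum is well defined
    lumbar_dip: float = 900.0
    lumbar_row: float = 95.0
    lumbar_sigma: float = 16.0
    sacral_amp: float = 4000.0
    sacral_row_l: float = 132.0
    sacral_row_r: float = 132.0
    sacral_sigma: float = 8.0
    sacral_lat_sigma: float = 12.0

    # scapulae
    scapula_amp_l: float = 3500.0
    scapula_amp_r: float = 3500.0
    scapula_row: float = 49.0
    scapula_offset: float = 16.5
    scapula_sigma_j: float = 6.0
    scapula_sigma_i: float = 6.0
    # local multiplicative gain around each scapula centre (ratio injection)
    scapula_gain_l: float = 1.0
    scapula_gain_r: float = 1.0
    scapula_gain_sigma: float = 7.0

    # shoulders: per-side cranial raise of the support top edge (px)
    shoulder_raise_l: float = 0.0
    shoulder_raise_r: float = 0.0

    # gluteal blobs
    glute_amp_l: float = 8000.0
    glute_amp_r: float = 8000.0
    glute_row_l: float = 140.0
    glute_row_r: float = 140.0
    glute_offset: float = 12.0
    glute_sigma_j: float = 8.0
    glute_sigma_i: float = 8.0

    # midline canal (multiplicative trough); lateral deviation polynomial in
    # the normalised row coordinate s = (j - canal_row0) / canal_row_scale
    canal_depth: float = 0.30
    canal_sigma: float = 2.5
    canal_coeffs: tuple[float, ...] = (0.0,)
    canal_row0: float = 75.0
    canal_row_scale: float = 45.0

    # waist concavity per side
    waist_depth_l: float = 0.18
    waist_depth_r: float = 0.18
    waist_row: float = 92.0
    waist_sigma: float = 9.0

    # one-sided multiplicative gain of the right half (side-scaling injection)
    side_gain_r: float = 1.0
    side_gain_sigma: float = 2.0

    # unilateral intensity bump ("rib hump")
    hump_amp: float = 0.0
    hump_row: float = 70.0
    hump_col_offset: float = 14.0
    hump_sigma: float = 8.0

    # placement and noise
    rotation_deg: float = 0.0
    translation_px: int = 0
    noise_sigma: float = 0.0
    fold_probability: float = 0.0
    fold_amp: float = 16000.0

    def validate(self) -> None:
        n_rows, n_cols = self.shape
        if self.torso_length <= 0 or self.torso_length > n_rows:
            raise SpecError(f"torso_length {self.torso_length} outside the {n_rows}-row grid")
        if self.half_width <= 0 or 2 * self.half_width > n_cols:
            raise SpecError(f"half_width {self.half_width} outside the {n_cols}-column grid")
        if abs(self.rotation_deg) > 15:
            raise SpecError("placement rotation beyond the +/-15 degree alignment range")
        if abs(self.translation_px) > 30:
            raise SpecError("placement translation beyond the +/-30 px alignment range")
        if abs(self.translation_px) + self.half_width > (n_cols - 1) / 2:
            raise SpecError("translation places the torso outside the grid")
        for amp in (
            self.thoracic_amp, self.sacral_amp, self.scapula_amp_l, self.scapula_amp_r,
            self.glute_amp_l, self.glute_amp_r, self.hump_amp, self.base,
        ):
            if amp < 0:
                raise SpecError("amplitudes must be non-negative")


@dataclass
class GroundTruth:
    jts: int
    jtmax: int
    jlmin: int
    jsmax: int
    canal: np.ndarray  # canal column per row (before placement)
    waist_row: float
    waist_cols: tuple[float, float]  # (left, right) support waist apex columns
    shoulder_shift: float  # injected |raise_l - raise_r|
    pelvic_edge_shift: float  # expected P2 = 2 |glute_row_l - glute_row_r|
    scapula_gain_ratio: float  # expected SB4/SB5
    side_gain: float  # expected TS2/TS4/P4
    waist_depth_ratio: float  # expected W4
    rotation_deg: float
    translation_px: int


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-(((x - mu) / sigma) ** 2))


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[PressureFrame, GroundTruth]:
    spec.validate()
    rng = np.random.default_rng(seed)
    n_rows, n_cols = spec.shape
    axis = (n_cols - 1) / 2.0
    jj, ii = np.indices(spec.shape, dtype=float)
    di = ii - axis
    left = di < 0

    # support: per-side top edge with rounded shoulder corners
    top0 = n_rows - spec.torso_length
    raise_side = np.where(left, spec.shoulder_raise_l, spec.shoulder_raise_r)
    xi = np.abs(di) / spec.half_width
    top = top0 - raise_side + spec.cap_rows * np.clip(xi, 0.0, 1.2) ** 4

    depth_side = np.where(left, spec.waist_depth_l, spec.waist_depth_r)
    half_width = spec.half_width * (
        1.0 - depth_side * _gauss(jj, spec.waist_row, spec.waist_sigma)
    )
    support = np.clip((half_width - np.abs(di)) / spec.edge_taper, 0.0, 1.0)
    support *= np.clip((jj - top) / spec.edge_taper, 0.0, 1.0)

    f = np.full(spec.shape, spec.base)
    f += (
        spec.thoracic_amp
        * _gauss(jj, spec.thoracic_row, spec.thoracic_sigma)
        * _gauss(di, 0.0, spec.thoracic_lat_sigma)
    )
    f -= spec.lumbar_dip * _gauss(jj, spec.lumbar_row, spec.lumbar_sigma)
    sacral_row_side = np.where(left, spec.sacral_row_l, spec.sacral_row_r)
    f += (
        spec.sacral_amp
        * _gauss(jj, sacral_row_side, spec.sacral_sigma)
        * _gauss(di, 0.0, spec.sacral_lat_sigma)
    )
    for amp, col in (
        (spec.scapula_amp_l, axis - spec.scapula_offset),
        (spec.scapula_amp_r, axis + spec.scapula_offset),
    ):
        f += amp * _gauss(jj, spec.scapula_row, spec.scapula_sigma_j) * _gauss(
            ii, col, spec.scapula_sigma_i
        )
    for amp, row, col in (
        (spec.glute_amp_l, spec.glute_row_l, axis - spec.glute_offset),
        (spec.glute_amp_r, spec.glute_row_r, axis + spec.glute_offset),
    ):
        f += amp * _gauss(jj, row, spec.glute_sigma_j) * _gauss(ii, col, spec.glute_sigma_i)
    if spec.hump_amp:
        f += spec.hump_amp * _gauss(jj, spec.hump_row, spec.hump_sigma) * _gauss(
            ii, axis + spec.hump_col_offset, spec.hump_sigma
        )

    image = f * support

    # midline canal along a polynomial lateral-deviation path
    s = (jj - spec.canal_row0) / spec.canal_row_scale
    deviation = np.zeros_like(jj)
    for power, coeff in enumerate(spec.canal_coeffs):
        deviation += coeff * s**power
    canal_col = axis + deviation
    image *= 1.0 - spec.canal_depth * np.exp(-(((ii - canal_col) / spec.canal_sigma) ** 2))

    # local scapula gains and right-half gain
    for gain, col in (
        (spec.scapula_gain_l, axis - spec.scapula_offset),
        (spec.scapula_gain_r, axis + spec.scapula_offset),
    ):
        if gain != 1.0:
            bump = _gauss(jj, spec.scapula_row, spec.scapula_gain_sigma) * _gauss(
                ii, col, spec.scapula_gain_sigma
            )
            image *= 1.0 + (gain - 1.0) * bump
    if spec.side_gain_r != 1.0:
        logistic = 1.0 / (1.0 + np.exp(-di / spec.side_gain_sigma))
        image *= 1.0 + (spec.side_gain_r - 1.0) * logistic

    # ground truth from the clean, unplaced image
    rows = np.arange(n_rows)
    band = slice(n_cols // 2 - 16, n_cols // 2 + 15)  # matches the z(j) band
    z_clean = image[:, band].mean(axis=1)
    row_sums = image.sum(axis=1)
    filled = np.nonzero(row_sums > 7000.0)[0]
    jts_true = int(filled[0]) if filled.size else 0
    mid = int((spec.thoracic_row + (spec.sacral_row_l + spec.sacral_row_r) / 2) / 2)
    jtmax_true = int(np.argmax(z_clean[:mid]))
    jsmax_true = mid + int(np.argmax(z_clean[mid:]))
    jlmin_true = jtmax_true + int(np.argmin(z_clean[jtmax_true : jsmax_true + 1]))
    truth = GroundTruth(
        jts=jts_true,
        jtmax=jtmax_true,
        jlmin=jlmin_true,
        jsmax=jsmax_true,
        canal=axis + np.polyval(list(spec.canal_coeffs[::-1]), (rows - spec.canal_row0) / spec.canal_row_scale),
        waist_row=spec.waist_row,
        waist_cols=(
            axis - spec.half_width * (1 - spec.waist_depth_l),
            axis + spec.half_width * (1 - spec.waist_depth_r),
        ),
        shoulder_shift=abs(spec.shoulder_raise_l - spec.shoulder_raise_r),
        pelvic_edge_shift=2.0 * abs(spec.glute_row_l - spec.glute_row_r),
        scapula_gain_ratio=max(
            spec.scapula_gain_l / spec.scapula_gain_r,
            spec.scapula_gain_r / spec.scapula_gain_l,
        ),
        side_gain=max(spec.side_gain_r, 1.0 / spec.side_gain_r),
        waist_depth_ratio=(
            max(spec.waist_depth_l / spec.waist_depth_r, spec.waist_depth_r / spec.waist_depth_l)
            if spec.waist_depth_l > 0 and spec.waist_depth_r > 0
            else float("nan")
        ),
        rotation_deg=spec.rotation_deg,
        translation_px=spec.translation_px,
    )

    # placement
    if spec.rotation_deg:
        image = ndimage.rotate(image, spec.rotation_deg, reshape=False, order=1, mode="constant", cval=0.0)
        image = np.clip(image, 0.0, None)
    t = int(spec.translation_px)
    if t:
        shifted = np.zeros_like(image)
        if t > 0:
            shifted[:, t:] = image[:, :-t]
        else:
            shifted[:, :t] = image[:, -t:]
        image = shifted

    # sensor noise and fold artifacts
    if spec.noise_sigma:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    if spec.fold_probability:
        if rng.random() < spec.fold_probability:
            image[rng.integers(0, n_rows), :] += spec.fold_amp
        if rng.random() < spec.fold_probability:
            image[:, rng.integers(0, n_cols)] += spec.fold_amp
    image = np.clip(image, 0.0, None)
    return PressureFrame(values=image, pixel_mm=spec.pixel_mm), truth


def generate_recording(
    spec: PhantomSpec,
    seed: int | None = None,
    n_frames: int = 10,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    breathing_amp: float = 0.01,
    subject_id: str = "",
    repetition_id: str = "",
) -> tuple[Recording, GroundTruth]:
    """A short recording: the phantom modulated by a breathing sine plus
    per-frame noise, so the medial-frame rule has work to do."""
    rng = np.random.default_rng(seed)
    base_frame, truth = generate_phantom(spec, seed=seed)
    frames = []
    for k in range(n_frames):
        phase = 2.0 * np.pi * k / max(1, n_frames)
        factor = 1.0 + breathing_amp * np.sin(phase)
        values = base_frame.values * factor
        if spec.noise_sigma:
            values = np.clip(values + rng.normal(0.0, spec.noise_sigma / 2, size=values.shape), 0.0, None)
        frames.append(PressureFrame(values=values, pixel_mm=spec.pixel_mm))
    rec = Recording(
        frames=frames,
        sample_rate_hz=sample_rate_hz,
        subject_id=subject_id,
        repetition_id=repetition_id,
    )
    return rec, truth


@dataclass
class StudySpec:
    """Population model for a repeated-measurement study.

    Between-subject variation perturbs the degree knobs of the phantom;
    within-subject variation re-draws placement and adds small intensity
    jitter, emulating repositioning between repetitions.
    """

    n_subjects: int = 40
    k_repetitions: int = 10
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)

    # between-subject standard deviations
    torso_length_sd: float = 5.0
    half_width_sd: float = 2.0
    thoracic_amp_sd: float = 900.0
    sacral_amp_sd: float = 600.0
    glute_amp_sd: float = 500.0
    waist_depth_sd: float = 0.03
    base_sd: float = 300.0

    # within-subject (repositioning) variation
    rotation_sd_deg: float = 2.0
    translation_sd_px: float = 3.0
    amp_jitter: float = 0.02
    noise_sigma: float = 100.0

    n_frames: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.k_repetitions < 2:
            raise SpecError("a study needs >= 2 subjects and >= 2 repetitions")


def _subject_spec(study: StudySpec, rng: np.random.Generator) -> PhantomSpec:
    b = study.base_spec
    spec = dataclasses.replace(
        b,
        torso_length=float(np.clip(b.torso_length + rng.normal(0, study.torso_length_sd), 100, b.shape[0] - 10)),
        half_width=float(np.clip(b.half_width + rng.normal(0, study.half_width_sd), 18, b.shape[1] / 2 - 10)),
        thoracic_amp=float(max(500.0, b.thoracic_amp + rng.normal(0, study.thoracic_amp_sd))),
        sacral_amp=float(max(500.0, b.sacral_amp + rng.normal(0, study.sacral_amp_sd))),
        glute_amp_l=float(max(500.0, b.glute_amp_l + rng.normal(0, study.glute_amp_sd))),
        base=float(max(3000.0, b.base + rng.normal(0, study.base_sd))),
    )
    depth = float(np.clip(b.waist_depth_l + rng.normal(0, study.waist_depth_sd), 0.08, 0.30))
    spec = dataclasses.replace(spec, waist_depth_l=depth, waist_depth_r=depth, glute_amp_r=spec.glute_amp_l)
    return spec


def generate_study(
    study: StudySpec,
) -> Iterator[tuple[str, str, Recording, GroundTruth]]:
    """Yield (subject_id, repetition_id, recording, truth) for n x k cells."""
    rng = np.random.default_rng(study.seed)
    for s in range(study.n_subjects):
        subject = _subject_spec(study, rng)
        sid = f"S{s:03d}"
        for r in range(study.k_repetitions):
            rep = dataclasses.replace(
                subject,
                rotation_deg=float(np.clip(rng.normal(0, study.rotation_sd_deg), -10, 10)),
                translation_px=int(np.clip(round(rng.normal(0, study.translation_sd_px)), -10, 10)),
                thoracic_amp=subject.thoracic_amp * (1 + rng.normal(0, study.amp_jitter)),
                sacral_amp=subject.sacral_amp * (1 + rng.normal(0, study.amp_jitter)),
                base=subject.base * (1 + rng.normal(0, study.amp_jitter / 2)),
                noise_sigma=study.noise_sigma,
            )
            rid = f"R{r:03d}"
            rec, truth = generate_recording(
                rep,
                seed=int(rng.integers(0, 2**31)),
                n_frames=study.n_frames,
                subject_id=sid,
                repetition_id=rid,
            )
            yield sid, rid, rec, truth


def spec_from_yaml(path: str | Path) -> PhantomSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(data) - known
    if unknown:
        raise SpecError(f"unknown phantom spec keys: {sorted(unknown)}")
    if "shape" in data:
        data["shape"] = tuple(data["shape"])
    if "canal_coeffs" in data:
        data["canal_coeffs"] = tuple(data["canal_coeffs"])
    return PhantomSpec(**data)
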
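"""End-to-end orchestration: recording -> parameter set; study -> table.

Parameter families fail independently: a failed waist fit is recorded per
parameter and never voids the sagittal parameters. Landmark detection is
the only hard prerequisite; its failure is recorded for every dependent
parameter.

Reported values use the 1-based row/column convention of the literature;
internal computation stays 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import lumbopelvic_params as lumbo
from . import spine_params as spine
from . import thoracic_params as thoracic
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import PipelineError, TorsobaroError
from .landmarks import detect_landmarks, reference_distances
from .preprocess import align, filter_frames, fit_roi
from .pressure_io import Recording, read_recording, select_medial_frame
from .reliability import MeasurementMatrix, reliability_table


@dataclass
class ParamValue:
    value: float
    units: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class ParameterSet:
    params: dict[str, ParamValue] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    transform: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""
    subject_id: str = ""
    repetition_id: str = ""

    def add(self, name: str, value: float, units: str, warnings: list[str] | None = None) -> None:
        self.params[name] = ParamValue(float(value), units, list(warnings or []))

    def fail(self, names: Iterable[str], message: str) -> None:
        for name in names:
            self.failures[name] = message

    def value(self, name: str) -> float:
        return self.params[name].value

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "repetition_id": self.repetition_id,
            "config_hash": self.config_hash,
            "transform": self.transform,
            "parameters": {
                k: {"value": v.value, "units": v.units, "warnings": v.warnings}
                for k, v in sorted(self.params.items())
            },
            "failures": dict(sorted(self.failures.items())),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


FC_NAMES = ["FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FC7"]
SC_NAMES = [f"SC{k}" for k in range(1, 9)]
S_NAMES = ["S0_l", "S0_r", "S1", "S2", "S2_l", "S2_r"]
SB_NAMES = ["SB0_vl", "SB0_vr", "SB0_hl", "SB0_hr", "SB1", "SB2", "SB3", "SB4", "SB4_l", "SB4_r", "SB5", "SB5_l", "SB5_r"]
TS_NAMES = ["TS1", "TS2", "TS2_l", "TS2_r", "TS3", "TS3_l", "TS3_r", "TS4", "TS4_l", "TS4_r", "TS5"]
W_NAMES = ["W0_vl", "W0_vr", "W0_hl", "W0_hr", "W1", "W2", "W3", "W4", "W4_l", "W4_r"]
P_NAMES = ["P0_ul", "P0_ur", "P0_ll", "P0_lr", "P1", "P2", "P3", "P3_l", "P3_r", "P4", "P4_l", "P4_r"]
LANDMARK_NAMES = ["jts", "jt", "jtmax", "jtl", "jlmin", "jl", "jsmax", "il", "ir"]
DISTANCE_NAMES = ["dl", "dw", "dth", "dlu", "ds"]

ALL_PARAM_NAMES = (
    LANDMARK_NAMES + DISTANCE_NAMES + FC_NAMES + SC_NAMES + S_NAMES
    + SB_NAMES + TS_NAMES + W_NAMES + P_NAMES
)

# units of parameters whose reliability rows get an mm column
PX_UNITS = {
    **{n: "px" for n in LANDMARK_NAMES + DISTANCE_NAMES},
    "FC1": "px", "FC2": "px^2", "FC3": "n.d.", "FC4": "px", "FC5": "px", "FC6": "px", "FC7": "n.d.",
    **{n: "n.d." for n in SC_NAMES},
    "S0_l": "px", "S0_r": "px", "S1": "px", "S2": "n.d.", "S2_l": "n.d.", "S2_r": "n.d.",
    "SB0_vl": "px", "SB0_vr": "px", "SB0_hl": "px", "SB0_hr": "px",
    "SB1": "px", "SB2": "px", "SB3": "deg",
    "SB4": "n.d.", "SB4_l": "prv", "SB4_r": "prv", "SB5": "n.d.", "SB5_l": "prv", "SB5_r": "prv",
    "TS1": "px", "TS2": "n.d.", "TS2_l": "prv", "TS2_r": "prv",
    "TS3": "n.d.", "TS3_l": "prv", "TS3_r": "prv",
    "TS4": "n.d.", "TS4_l": "prv", "TS4_r": "prv", "TS5": "%",
    "W0_vl": "px", "W0_vr": "px", "W0_hl": "px", "W0_hr": "px",
    "W1": "px", "W2": "px", "W3": "deg", "W4": "n.d.", "W4_l": "n.d.", "W4_r": "n.d.",
    "P0_ul": "px", "P0_ur": "px", "P0_ll": "px", "P0_lr": "px",
    "P1": "prv/px", "P2": "px", "P3": "n.d.", "P3_l": "prv", "P3_r": "prv",
    "P4": "n.d.", "P4_l": "prv", "P4_r": "prv",
}


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def analyze_recording(
    rec: Recording, config: PipelineConfig = DEFAULT_CONFIG
) -> ParameterSet:
    frame = select_medial_frame(rec)
    return analyze_frame(frame, config, subject_id=rec.subject_id, repetition_id=rec.repetition_id)


def analyze_frame(
    frame, config: PipelineConfig = DEFAULT_CONFIG, subject_id: str = "", repetition_id: str = ""
) -> ParameterSet:
    ps = ParameterSet(
        config_hash=_config_hash(config), subject_id=subject_id, repetition_id=repetition_id
    )
    try:
        I, Is = filter_frames(frame)
        aligned = align(I, Is, config)
    except TorsobaroError as exc:
        raise PipelineError("align", str(exc)) from exc
    ps.transform = {
        "alpha_deg": aligned.alpha_deg,
        "tc_px": aligned.tc_px,
        "bottom_shift_px": aligned.bottom_shift_px,
    }
    try:
        roi = fit_roi(aligned.I, config)
    except TorsobaroError as exc:
        raise PipelineError("roi", str(exc)) from exc
    ps.transform.update({"roi_sj": roi.sj, "roi_si": roi.si})

    try:
        lm = detect_landmarks(aligned, roi, config)
    except TorsobaroError as exc:
        ps.fail(ALL_PARAM_NAMES, f"landmarks: {exc}")
        return ps

    # landmarks and distances, reported 1-based
    for name in LANDMARK_NAMES:
        ps.add(name, getattr(lm, name) + 1, "px")
    dist = reference_distances(lm)
    for name in DISTANCE_NAMES:
        ps.add(name, getattr(dist, name), "px")

    try:
        fc = spine.extract_frontal_curve(roi, lm, config)
        fp = spine.frontal_params(fc, lm)
        for k, name in enumerate(FC_NAMES, start=1):
            ps.add(name, getattr(fp, f"fc{k}"), PX_UNITS[name], fp.warnings)
    except TorsobaroError as exc:
        ps.fail(FC_NAMES, f"frontal curve: {exc}")

    try:
        sp = spine.sagittal_params(lm)
        for k, name in enumerate(SC_NAMES, start=1):
            ps.add(name, getattr(sp, f"sc{k}"), "n.d.", sp.warnings)
    except TorsobaroError as exc:
        ps.fail(SC_NAMES, f"sagittal profile: {exc}")

    try:
        sh = thoracic.shoulder_params(roi, lm, config)
        ps.add("S0_l", sh.js_l + 1, "px", sh.warnings)
        ps.add("S0_r", sh.js_r + 1, "px")
        ps.add("S1", sh.s1, "px")
        ps.add("S2", sh.s2, "n.d.")
        ps.add("S2_l", sh.s2_l, "n.d.")
        ps.add("S2_r", sh.s2_r, "n.d.")
    except TorsobaroError as exc:
        ps.fail(S_NAMES, f"shoulder contour: {exc}")

    centres = None
    try:
        centres = thoracic.locate_scapulae(aligned.Is, lm, config)
        sb = thoracic.scapula_params(aligned.Is, centres)
        ps.add("SB0_vl", sb.sb0_vl + 1, "px", sb.warnings)
        ps.add("SB0_vr", sb.sb0_vr + 1, "px")
        ps.add("SB0_hl", sb.sb0_hl, "px")
        ps.add("SB0_hr", sb.sb0_hr, "px")
        for name, val in (
            ("SB1", sb.sb1), ("SB2", sb.sb2), ("SB3", sb.sb3),
            ("SB4", sb.sb4), ("SB4_l", sb.sb4_l), ("SB4_r", sb.sb4_r),
            ("SB5", sb.sb5), ("SB5_l", sb.sb5_l), ("SB5_r", sb.sb5_r),
        ):
            ps.add(name, val, PX_UNITS[name])
    except TorsobaroError as exc:
        ps.fail(SB_NAMES, f"scapulae: {exc}")

    if centres is not None:
        try:
            ts = thoracic.torso_symmetry_params(roi, lm, centres, config)
            for name, val in (
                ("TS1", ts.ts1), ("TS2", ts.ts2), ("TS2_l", ts.ts2_l), ("TS2_r", ts.ts2_r),
                ("TS3", ts.ts3), ("TS3_l", ts.ts3_l), ("TS3_r", ts.ts3_r),
                ("TS4", ts.ts4), ("TS4_l", ts.ts4_l), ("TS4_r", ts.ts4_r), ("TS5", ts.ts5),
            ):
                ps.add(name, val, PX_UNITS[name], ts.warnings if name == "TS1" else None)
        except TorsobaroError as exc:
            ps.fail(TS_NAMES, f"torso symmetry: {exc}")
    else:
        ps.fail(TS_NAMES, "torso symmetry skipped: scapula centres unavailable")

    try:
        w = lumbo.waist_params(roi, lm, config)
        ps.add("W0_vl", w.w0_vl + 1, "px", w.warnings)
        ps.add("W0_vr", w.w0_vr + 1, "px")
        ps.add("W0_hl", w.w0_hl, "px")
        ps.add("W0_hr", w.w0_hr, "px")
        for name, val in (
            ("W1", w.w1), ("W2", w.w2), ("W3", w.w3),
            ("W4", w.w4), ("W4_l", w.w4_l), ("W4_r", w.w4_r),
        ):
            ps.add(name, val, PX_UNITS[name])
    except TorsobaroError as exc:
        ps.fail(W_NAMES, f"waist contour: {exc}")

    try:
        ps.add("P1", lumbo.sacral_slope(lm), "prv/px")
    except TorsobaroError as exc:
        ps.fail(["P1"], f"sacral slope: {exc}")

    try:
        p = lumbo.pelvic_params(roi, lm, config)
        ps.add("P0_ul", p.jpu_l + 1, "px", p.warnings)
        ps.add("P0_ur", p.jpu_r + 1, "px")
        ps.add("P0_ll", p.jpl_l + 1, "px")
        ps.add("P0_lr", p.jpl_r + 1, "px")
        for name, val in (
            ("P2", p.p2), ("P3", p.p3), ("P3_l", p.p3_l), ("P3_r", p.p3_r),
            ("P4", p.p4), ("P4_l", p.p4_l), ("P4_r", p.p4_r),
        ):
            ps.add(name, val, PX_UNITS[name])
    except TorsobaroError as exc:
        ps.fail([n for n in P_NAMES if n != "P1"], f"pelvic contour: {exc}")

    return ps


def parameter_matrices(
    results: list[ParameterSet],
) -> dict[str, MeasurementMatrix]:
    """Pivot per-recording parameter sets into subjects x repetitions
    matrices, one per parameter; missing cells become NaN."""
    rows = []
    for ps in results:
        for name, pv in ps.params.items():
            rows.append((ps.subject_id, ps.repetition_id, name, pv.value))
        for name in ps.failures:
            rows.append((ps.subject_id, ps.repetition_id, name, np.nan))
    frame = pd.DataFrame(rows, columns=["subject", "repetition", "parameter", "value"])
    matrices = {}
    for name, group in frame.groupby("parameter", sort=True):
        pivot = group.pivot_table(
            index="subject", columns="repetition", values="value", aggfunc="first", dropna=False
        )
        matrices[name] = MeasurementMatrix(
            values=pivot.to_numpy(), parameter_name=name, units=PX_UNITS.get(name, "")
        )
    return matrices


def analyze_study(
    recordings: Iterable[Recording], config: PipelineConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, list[ParameterSet]]:
    results = []
    for rec in recordings:
        try:
            results.append(analyze_recording(rec, config))
        except PipelineError as exc:
            ps = ParameterSet(subject_id=rec.subject_id, repetition_id=rec.repetition_id)
            ps.fail(ALL_PARAM_NAMES, str(exc))
            results.append(ps)
    if not results:
        raise PipelineError("study", "no recordings found")
    pixel_mm = 5.1
    table = reliability_table(parameter_matrices(results), pixel_mm=pixel_mm)
    return table, results


def read_study_directory(path: str | Path) -> list[Recording]:
    """Every subdirectory holding frame CSVs is one recording; subject and
    repetition labels come from the sidecar."""
    path = Path(path)
    recs = []
    for sub in sorted(p for p in path.iterdir() if p.is_dir()):
        if any(sub.glob("frame_*.csv")):
            recs.append(read_recording(sub))
    return recs
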
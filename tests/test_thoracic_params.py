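from __future__ import annotations

import numpy as np
import pytest

import torsobaro as tb
from conftest import run_stages
from torsobaro.errors import DetectionError, UndefinedRatioError
from torsobaro.landmarks import detect_landmarks
from torsobaro.preprocess import RoiImage
from torsobaro.pressure_io import PressureFrame
from torsobaro.thoracic_params import (
    ScapulaCentres,
    locate_scapulae,
    max_ratio,
    scapula_params,
    shoulder_params,
    torso_symmetry_params,
)

from test_spine_params import make_landmarks


class TestMaxRatio:
    def test_ordering_free(self):
        assert max_ratio(2.0, 4.0) == 2.0
        assert max_ratio(4.0, 2.0) == 2.0

    def test_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.random(2) + 0.1
            assert max_ratio(a, b) >= 1.0

    def test_non_positive_rejected(self):
        with pytest.raises(UndefinedRatioError):
            max_ratio(0.0, 1.0)


class TestShoulderParams:
    def test_symmetric_phantom_identities(self, sym_chain, config):
        _, roi, lm, _ = sym_chain
        sh = shoulder_params(roi, lm, config)
        assert sh.s1 == 0
        assert sh.s2 == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("d", [2, 3])
    def test_raised_shoulder_recovered(self, d, config):
        frame, truth = tb.generate_phantom(tb.PhantomSpec(shoulder_raise_l=d), seed=0)
        _, roi, lm = run_stages(frame, config)
        sh = shoulder_params(roi, lm, config)
        assert sh.s1 == pytest.approx(truth.shoulder_shift, abs=1)
        assert sh.s1_signed < 0  # left edge is more cranial (smaller row)

    def test_slopes_match_closed_form_regression(self, sym_chain, config):
        _, roi, lm, _ = sym_chain
        sh = shoulder_params(roi, lm, config)
        for (cols, rows), slope in (
            (sh.contour_l, sh.ms_l),
            (sh.contour_r, sh.ms_r),
        ):
            x = cols.astype(float)
            y = rows.astype(float)
            expected = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
            assert slope == pytest.approx(expected, abs=1e-9)

    def test_empty_region_raises(self, config):
        values = np.zeros((160, 100))
        values[100:160, 30:70] = 100.0  # nothing in the upper third
        roi = RoiImage(frame=PressureFrame(values=values), mask=values > 0, sj=1, si=1)
        lm = make_landmarks(np.full(160, 1.0))
        with pytest.raises(DetectionError):
            shoulder_params(roi, lm, config)


def synthetic_is(peaks) -> PressureFrame:
    """Lightly filtered image stand-in: Gaussian blobs on a quiet floor."""
    values = np.full((160, 100), 7500.0)
    jj, ii = np.indices(values.shape, dtype=float)
    for amp, j0, i0, sigma in peaks:
        values += amp * np.exp(-(((jj - j0) / sigma) ** 2 + ((ii - i0) / sigma) ** 2))
    return PressureFrame(values=values)


class TestLocateScapulae:
    def test_unique_maxima_recovered_exactly(self, config):
        Is = synthetic_is([(5000, 49, 30, 5.0), (5000, 49, 69, 5.0)])
        lm = make_landmarks(np.full(160, 1.0))
        c = locate_scapulae(Is, lm, config)
        assert (c.jsb_l, c.isb_l) == (49, 30)
        assert (c.jsb_r, c.isb_r) == (49, 69)

    def test_lateral_candidate_wins_over_stronger_medial(self, config):
        # two clear maxima on the left: medial one stronger, lateral selected
        Is = synthetic_is(
            [(6000, 50, 34, 4.0), (4000, 48, 18, 4.0), (5000, 49, 69, 5.0)]
        )
        lm = make_landmarks(np.full(160, 1.0))
        c = locate_scapulae(Is, lm, config)
        assert (c.jsb_l, c.isb_l) == (48, 18)

    def test_symmetric_phantom_offsets_match(self, sym_chain, config):
        aligned, _, lm, _ = sym_chain
        c = locate_scapulae(aligned.Is, lm, config)
        axis = aligned.Is.axis_col
        assert abs(abs(c.isb_l - axis) - abs(c.isb_r - axis)) <= 1
        assert c.jsb_l == c.jsb_r

    def test_empty_interval_raises(self, config):
        Is = PressureFrame(values=np.zeros((160, 100)))
        lm = make_landmarks(np.full(160, 1.0))
        with pytest.raises(DetectionError, match="scapula"):
            locate_scapulae(Is, lm, config)


class TestScapulaParams:
    def test_identical_windows_identities(self):
        Is = synthetic_is([(5000, 49, 30, 5.0), (5000, 49, 69, 5.0)])
        c = ScapulaCentres(jsb_l=49, isb_l=30, jsb_r=49, isb_r=69)
        sb = scapula_params(Is, c)
        assert sb.sb1 == 0 and sb.sb2 == pytest.approx(0, abs=1e-9)
        assert sb.sb3 == pytest.approx(0.0)
        assert sb.sb4 == pytest.approx(1.0, abs=1e-9)
        assert sb.sb5 == pytest.approx(1.0, abs=1e-9)

    def test_right_window_scaled_exact_ratio(self):
        values = np.full((160, 100), 1000.0)
        rng = np.random.default_rng(5)
        win = rng.random((11, 11)) * 500 + 500
        values[44:55, 25:36] = win
        values[44:55, 64:75] = 1.2 * win
        Is = PressureFrame(values=values)
        c = ScapulaCentres(jsb_l=49, isb_l=30, jsb_r=49, isb_r=69)
        sb = scapula_params(Is, c)
        assert sb.sb4 == pytest.approx(1.2, abs=1e-12)
        assert sb.sb5 == pytest.approx(1.2, abs=1e-12)

    def test_matches_naive_window_oracle(self):
        rng = np.random.default_rng(6)
        values = rng.random((160, 100)) * 1000 + 1
        Is = PressureFrame(values=values)
        c = ScapulaCentres(jsb_l=50, isb_l=28, jsb_r=47, isb_r=71)
        sb = scapula_params(Is, c)
        wl = values[45:56, 23:34]
        wr = values[42:53, 66:77]
        assert sb.sb4_l == wl.max() and sb.sb4_r == wr.max()
        assert sb.sb5_l == pytest.approx(wl.mean(), abs=1e-9)
        assert sb.sb1 == 3
        assert sb.sb3 == pytest.approx(
            abs(np.degrees(np.arctan((47 - 50) / (71 - 28)))), abs=1e-9
        )

    def test_clipped_window_warns(self):
        Is = synthetic_is([])
        c = ScapulaCentres(jsb_l=2, isb_l=3, jsb_r=49, isb_r=69)
        sb = scapula_params(Is, c)
        assert any("clipped" in w for w in sb.warnings)


def symmetric_roi() -> tuple[RoiImage, ScapulaCentres]:
    values = np.zeros((160, 100))
    jj, ii = np.indices(values.shape, dtype=float)
    blob = 9000.0 * np.exp(-(((jj - 80) / 45) ** 2 + ((ii - 49.5) / 22) ** 2))
    mask = blob > 1500.0
    values = blob * mask
    roi = RoiImage(frame=PressureFrame(values=values), mask=mask, sj=1, si=1)
    centres = ScapulaCentres(jsb_l=45, isb_l=33, jsb_r=45, isb_r=66)
    return roi, centres


class TestTorsoSymmetry:
    def test_symmetric_identities(self, config):
        roi, centres = symmetric_roi()
        lm = make_landmarks(np.full(160, 1.0))
        ts = torso_symmetry_params(roi, lm, centres, config)
        assert ts.ts1 == pytest.approx(0.0, abs=1e-9)
        assert ts.ts2 == pytest.approx(1.0, abs=1e-12)
        assert ts.ts3 == pytest.approx(1.0, abs=1e-12)
        assert ts.ts4 == pytest.approx(1.0, abs=1e-12)
        assert ts.ts5 == pytest.approx(0.0, abs=1e-12)

    def test_right_half_scaling_identity(self, config):
        roi, centres = symmetric_roi()
        r = 1.3
        scaled = roi.frame.values.copy()
        scaled[:, 50:] *= r
        roi2 = RoiImage(
            frame=PressureFrame(values=scaled), mask=roi.mask, sj=1, si=1
        )
        lm = make_landmarks(np.full(160, 1.0))
        ts = torso_symmetry_params(roi2, lm, centres, config)
        assert ts.ts2 == pytest.approx(r, abs=1e-9)
        assert ts.ts3 == pytest.approx(r, abs=1e-9)
        assert ts.ts4 == pytest.approx(r, abs=1e-9)

    def test_ts5_invariant_to_global_scaling(self, config):
        frame, _ = tb.generate_phantom(tb.PhantomSpec(hump_amp=1500.0), seed=4)
        _, roi, lm = run_stages(frame, config)
        centres = locate_scapulae(run_stages(frame, config)[0].Is, lm, config)
        ts1 = torso_symmetry_params(roi, lm, centres, config)
        roi_scaled = RoiImage(
            frame=PressureFrame(values=roi.frame.values * 3.0), mask=roi.mask, sj=1, si=1
        )
        ts2 = torso_symmetry_params(roi_scaled, lm, centres, config)
        assert ts2.ts5 == pytest.approx(ts1.ts5, rel=1e-9)

    def test_matches_double_loop_oracle(self, config):
        frame, _ = tb.generate_phantom(
            tb.PhantomSpec(hump_amp=1200.0, side_gain_r=1.05), seed=5
        )
        aligned, roi, lm = run_stages(frame, config)
        centres = locate_scapulae(aligned.Is, lm, config)
        ts = torso_symmetry_params(roi, lm, centres, config)

        values, mask = roi.frame.values, roi.mask
        axis = 49.5

        def region(rows, cols):
            out = []
            for j in range(rows[0], rows[1] + 1):
                for i in range(cols[0], cols[1] + 1):
                    if mask[j, i]:
                        out.append(values[j, i])
            return np.array(out)

        t_l = region((lm.jts, lm.jlmin), (max(0, lm.il - 10), 49))
        t_r = region((lm.jts, lm.jlmin), (50, min(99, lm.ir + 10)))
        half = (lm.ir - lm.il) / 2
        tl_l = region((centres.jsb_l + 10, lm.jl), (int(np.ceil(axis - half)), 49))
        tl_r = region((centres.jsb_r + 10, lm.jl), (50, int(np.floor(axis + half))))
        assert ts.ts2 == pytest.approx(max_ratio(tl_l.mean(), tl_r.mean()), abs=1e-9)
        assert ts.ts3 == pytest.approx(max_ratio(tl_l.max(), tl_r.max()), abs=1e-9)
        assert ts.ts4 == pytest.approx(max_ratio(t_l.sum(), t_r.sum()), abs=1e-9)

        # TS1 oracle
        total = 0.0
        for j in range(lm.jts, lm.jl + 1):
            row = values[j, lm.il : lm.ir + 1]
            if row.sum() > 0:
                cop = (np.arange(lm.il, lm.ir + 1) * row).sum() / row.sum()
                total += abs(cop - axis)
        assert ts.ts1 == pytest.approx(total, abs=1e-9)

        # TS5 oracle
        thr = values[mask].mean()
        seg = np.where(values > thr, values, 0.0)
        devs = []
        for j in range(lm.jts, lm.jlmin + 1):
            for i in range(100):
                if seg[j, i] > 0 and seg[j, 99 - i] > 0:
                    devs.append(abs(1 - seg[j, i] / seg[j, 99 - i]))
        assert ts.ts5 == pytest.approx(100 * np.mean(devs), abs=1e-9)

    def test_mirror_exactness_of_ratios(self, config):
        frame, _ = tb.generate_phantom(tb.PhantomSpec(hump_amp=1500.0), seed=4)
        aligned, roi, lm = run_stages(frame, config)
        centres = locate_scapulae(aligned.Is, lm, config)
        ts = torso_symmetry_params(roi, lm, centres, config)
        assert min(ts.ts2, ts.ts3, ts.ts4) >= 1.0

    def test_rib_hump_monotonicity(self, config):
        ts2s, ts4s, ts5s = [], [], []
        for amp in (0.0, 500.0, 1000.0, 1500.0, 2000.0):
            frame, _ = tb.generate_phantom(tb.PhantomSpec(hump_amp=amp), seed=0)
            aligned, roi, lm = run_stages(frame, config)
            centres = locate_scapulae(aligned.Is, lm, config)
            ts = torso_symmetry_params(roi, lm, centres, config)
            ts2s.append(ts.ts2)
            ts4s.append(ts.ts4)
            ts5s.append(ts.ts5)
        assert ts2s == sorted(ts2s)
        assert ts4s == sorted(ts4s)
        assert ts5s == sorted(ts5s)
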
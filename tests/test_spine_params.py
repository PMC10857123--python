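from __future__ import annotations

import math

import numpy as np
import pytest

import torsobaro as tb
from torsobaro.config import PipelineConfig
from torsobaro.errors import FitError
from torsobaro.landmarks import LandmarkSet, detect_landmarks
from torsobaro.preprocess import RoiImage
from torsobaro.pressure_io import PressureFrame
from torsobaro.spine_params import (
    FrontalCurve,
    extract_frontal_curve,
    frontal_params,
    sagittal_params,
)

AXIS = 49.5


def make_landmarks(z: np.ndarray, jts=30, jt=38, jtmax=52, jtl=70, jlmin=93,
                   jl=110, jsmax=130, il=24, ir=75) -> LandmarkSet:
    vz = float(z[jts : jlmin + 1].mean())
    return LandmarkSet(
        jts=jts, jt=jt, jtmax=jtmax, jtl=jtl, jlmin=jlmin, jl=jl, jsmax=jsmax,
        il=il, ir=ir, z=z, vz=vz, tv=7000.0, delta_iz=30, axis_col=AXIS,
        pixel_mm=5.1, n_rows=160,
    )


def canal_image(path) -> RoiImage:
    """Flat imprint with a Gaussian canal carved along path(j)."""
    values = np.zeros((160, 100))
    jj, ii = np.indices(values.shape, dtype=float)
    base = np.zeros_like(values)
    base[:, 15:85] = 10000.0
    centre = np.asarray([path(j) for j in range(160)])[:, None]
    canal = 1.0 - 0.4 * np.exp(-(((ii - centre) / 2.5) ** 2))
    values = base * canal
    return RoiImage(frame=PressureFrame(values=values), mask=values > 0, sj=1.0, si=1.0)


class TestFrontalCurve:
    def test_straight_canal_on_axis(self, config):
        roi = canal_image(lambda j: AXIS)
        lm = make_landmarks(np.full(160, 1.0))
        fc = extract_frontal_curve(roi, lm, config)
        np.testing.assert_allclose(fc.curve, AXIS, atol=0.05)
        assert abs(fc.slope) < 1e-6

    def test_cubic_canal_recovered(self, config):
        path = lambda j: AXIS + 2.0 * ((j - 74) / 40) ** 3 - 0.8 * ((j - 74) / 40)
        roi = canal_image(path)
        lm = make_landmarks(np.full(160, 1.0))
        fc = extract_frontal_curve(roi, lm, config)
        truth = np.asarray([path(j) for j in fc.rows])
        assert np.abs(fc.curve - truth).max() < 0.5

    def test_equidistant_minima_tie_to_smaller_column(self, config):
        values = np.zeros((160, 100))
        values[:, 35:65] = 1000.0
        values[:, 47] = 10.0  # two equidistant minima about the axis
        values[:, 52] = 10.0
        roi = RoiImage(frame=PressureFrame(values=values), mask=values > 0, sj=1.0, si=1.0)
        cfg = PipelineConfig(refine_canal_subpixel=False)
        lm = make_landmarks(np.full(160, 1.0))
        fc = extract_frontal_curve(roi, lm, cfg)
        np.testing.assert_allclose(fc.raw_minima, 47.0)

    def test_too_few_minima_raises(self, config):
        values = np.zeros((160, 100))
        values[40:44, 35:65] = 1000.0
        values[40:44, 49] = 10.0
        roi = RoiImage(frame=PressureFrame(values=values), mask=values > 0, sj=1.0, si=1.0)
        lm = make_landmarks(np.full(160, 1.0))
        with pytest.raises(FitError, match="underdetermined"):
            extract_frontal_curve(roi, lm, config)


def curve_fixture(values: np.ndarray, lm: LandmarkSet) -> FrontalCurve:
    rows = np.arange(lm.jt, lm.jl + 1)
    assert values.size == rows.size
    lin = np.polyfit(rows, values, 1)
    return FrontalCurve(
        rows=rows, curve=values, line=np.polyval(lin, rows), slope=float(lin[0]),
        intercept=float(lin[1]), raw_rows=rows, raw_minima=values, coeffs=np.array([]),
    )


class TestFrontalParams:
    def test_constant_curve_on_axis(self):
        lm = make_landmarks(np.full(160, 1.0))
        fc = curve_fixture(np.full(lm.jl - lm.jt + 1, AXIS), lm)
        fp = frontal_params(fc, lm)
        for v in (fp.fc1, fp.fc2, fp.fc4, fp.fc5, fp.fc6, fp.fc7):
            assert v == pytest.approx(0.0, abs=1e-9)
        assert fp.fc3 == pytest.approx(1.0)

    def test_linear_curve_closed_form(self):
        lm = make_landmarks(np.full(160, 1.0))
        rows = np.arange(lm.jt, lm.jl + 1)
        fc = curve_fixture(AXIS + 0.1 * (rows - lm.jt), lm)
        fp = frontal_params(fc, lm)
        assert fp.fc7 == pytest.approx(0.1)
        assert fp.fc5 == pytest.approx(0.1 * (lm.jl - lm.jt))
        assert fp.fc1 == pytest.approx(0.1 * (lm.jl - lm.jt))

    def test_matches_naive_summation_oracle(self):
        rng = np.random.default_rng(11)
        lm = make_landmarks(np.full(160, 1.0))
        rows = np.arange(lm.jt, lm.jl + 1)
        samples = AXIS + rng.normal(0, 2, size=rows.size)
        fc = curve_fixture(samples, lm)
        fp = frontal_params(fc, lm)

        # independent naive re-evaluation
        fc1 = sum(abs(samples[k] - samples[k + 1]) for k in range(samples.size - 1))
        mean = sum(samples) / samples.size
        fc2 = sum((s - mean) ** 2 for s in samples) / (samples.size - 1)
        dth = lm.jtl - lm.jt + 1
        dlu = lm.jl - lm.jtl + 1
        fc3 = (sum(samples[:dth]) / dth) / (sum(samples[dth - 1 :]) / dlu)
        fc4 = abs(sum(samples[:10]) - sum(samples[-10:])) / 10
        fc5 = max(abs(s - AXIS) for s in samples)
        fc6 = sum(abs(s - l) for s, l in zip(samples, fc.line))
        assert fp.fc1 == pytest.approx(fc1, abs=1e-9)
        assert fp.fc2 == pytest.approx(fc2, abs=1e-9)
        assert fp.fc3 == pytest.approx(fc3, abs=1e-9)
        assert fp.fc4 == pytest.approx(fc4, abs=1e-9)
        assert fp.fc5 == pytest.approx(fc5, abs=1e-9)
        assert fp.fc6 == pytest.approx(fc6, abs=1e-9)


class TestSagittalParams:
    def test_flat_profile_identities(self):
        lm = make_landmarks(np.full(160, 50.0))
        sp = sagittal_params(lm)
        for v in (sp.sc1, sp.sc2, sp.sc6):
            assert v == pytest.approx(0.0, abs=1e-9)
        for v in (sp.sc3, sp.sc5, sp.sc7, sp.sc8):
            assert v == pytest.approx(1.0, abs=1e-12)
        # the printed summed ratio divides unequal region lengths
        dth, dlu = lm.jtl - lm.jt + 1, lm.jl - lm.jtl + 1
        assert sp.sc4 == pytest.approx(dth / dlu, abs=1e-12)

    def test_piecewise_linear_slope_angle(self):
        # slopes +2 before and -1 after the thoracic maximum
        z = np.zeros(160)
        lm0 = make_landmarks(np.full(160, 1.0))
        jt, jtmax, jtl = lm0.jt, lm0.jtmax, lm0.jtl
        z[jt : jtmax + 1] = 2.0 * (np.arange(jt, jtmax + 1) - jt) + 10
        z[jtmax : jtl + 1] = z[jtmax] - 1.0 * (np.arange(jtmax, jtl + 1) - jtmax)
        z[jtl:] = z[jtl]
        z[:jt] = 10.0
        lm = make_landmarks(z)
        sp = sagittal_params(lm)
        assert sp.mt1 == pytest.approx(2.0)
        assert sp.mt2 == pytest.approx(-1.0)
        assert sp.sc1 == pytest.approx(math.atan((2 - (-1)) / (1 + 2 * (-1))))

    def test_matches_regression_and_ratio_oracle(self):
        j = np.arange(160, dtype=float)
        z = (
            4000.0
            + 5000.0 * np.exp(-(((j - 52) / 10) ** 2))
            + 6000.0 * np.exp(-(((j - 130) / 9) ** 2))
        )
        lm = make_landmarks(z)
        sp = sagittal_params(lm)

        def slope(a, b):
            # closed-form simple linear regression
            x = np.arange(a, b + 1, dtype=float)
            y = z[a : b + 1]
            return ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()

        mt1 = slope(lm.jt, lm.jtmax)
        mt2 = slope(lm.jtmax, lm.jtl)
        ml1 = slope(lm.jtl, lm.jlmin)
        ml2 = slope(lm.jlmin, lm.jl)
        assert sp.sc1 == pytest.approx(math.atan((mt1 - mt2) / (1 + mt1 * mt2)), abs=1e-9)
        assert sp.sc2 == pytest.approx(math.atan((ml1 - ml2) / (1 + ml1 * ml2)), abs=1e-9)
        assert sp.sc3 == pytest.approx(z[lm.jtmax] / z[lm.jlmin], abs=1e-12)
        thor = z[lm.jt : lm.jtl + 1].sum()
        lumb = z[lm.jtl : lm.jl + 1].sum()
        assert sp.sc4 == pytest.approx(thor / lumb, abs=1e-12)
        dth, dlu = lm.jtl - lm.jt + 1, lm.jl - lm.jtl + 1
        assert sp.sc5 == pytest.approx((thor / dth) / (lumb / dlu), abs=1e-12)
        assert sp.sc6 == pytest.approx(
            (z[lm.jtmax] - z[lm.jlmin]) / (lm.jtmax - lm.jlmin), abs=1e-12
        )
        assert sp.sc7 == pytest.approx(z[lm.jtmax] / lm.vz, abs=1e-12)
        assert sp.sc8 == pytest.approx(z[lm.jlmin] / lm.vz, abs=1e-12)

    def test_sc6_sign_convention_preserved(self):
        j = np.arange(160, dtype=float)
        z = 4000.0 + 5000.0 * np.exp(-(((j - 52) / 10) ** 2)) + 6000.0 * np.exp(
            -(((j - 130) / 9) ** 2)
        )
        lm = make_landmarks(z)
        sp = sagittal_params(lm)
        # z(jtmax) > z(jlmin) while jtmax < jlmin: the printed quotient is negative
        assert sp.sc6 < 0


class TestMirrorAndMonotonicity:
    def test_mirror_invariance(self, config, sym_phantom):
        frame, _ = tb.generate_phantom(
            tb.PhantomSpec(canal_coeffs=(0.5, 1.0), shoulder_raise_l=2.0), seed=3
        )
        mirrored = PressureFrame(values=frame.values[:, ::-1].copy())
        p0 = tb.analyze_frame(frame, config)
        p1 = tb.analyze_frame(mirrored, config)
        # z uses a 31-column band, which cannot be exactly mirror symmetric
        # on an even-width grid; invariance holds up to the band offset
        for name in [f"SC{k}" for k in range(1, 9)]:
            assert p1.value(name) == pytest.approx(
                p0.value(name), rel=0.05, abs=2e-3
            ), name
        for name in ("FC5", "FC6", "FC7", "FC4"):
            assert p1.value(name) == pytest.approx(p0.value(name), abs=0.25), name

    def test_kyphosis_amplitude_monotonicity(self, config):
        from conftest import run_stages

        sc3s, sc7s, sc6s = [], [], []
        for amp in (3000.0, 3750.0, 4500.0, 5250.0, 6000.0):
            frame, _ = tb.generate_phantom(tb.PhantomSpec(thoracic_amp=amp), seed=0)
            _, _, lm = run_stages(frame, config)
            sp = sagittal_params(lm)
            sc3s.append(sp.sc3)
            sc7s.append(sp.sc7)
            sc6s.append(abs(sp.sc6))
        assert sc3s == sorted(sc3s)
        assert sc7s == sorted(sc7s)
        assert sc6s == sorted(sc6s)
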
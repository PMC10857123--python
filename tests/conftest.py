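from __future__ import annotations

import numpy as np
import pytest

import torsobaro as tb
from torsobaro.config import PipelineConfig
from torsobaro.landmarks import detect_landmarks
from torsobaro.preprocess import align, filter_frames, fit_roi


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def sym_phantom():
    """Default symmetric phantom: zero noise, zero placement."""
    frame, truth = tb.generate_phantom(tb.PhantomSpec(), seed=0)
    return frame, truth


@pytest.fixture(scope="session")
def sym_chain(sym_phantom, config):
    """Filtered, aligned, ROI-masked symmetric phantom with landmarks."""
    frame, truth = sym_phantom
    I, Is = filter_frames(frame)
    aligned = align(I, Is, config)
    roi = fit_roi(aligned.I, config)
    lm = detect_landmarks(aligned, roi, config)
    return aligned, roi, lm, truth


def run_stages(frame, config, do_align: bool = True):
    """Filter + align + ROI + landmarks for a single frame.

    ``do_align=False`` applies an identity transform instead, for tests of
    intensity-asymmetry recovery on already-centred phantoms (the symmetry
    alignment legitimately absorbs part of a pure side gain by translating).
    """
    from torsobaro.preprocess import AlignedImages

    I, Is = filter_frames(frame)
    if do_align:
        aligned = align(I, Is, config)
    else:
        aligned = AlignedImages(I=I, Is=Is, alpha_deg=0, tc_px=0, bottom_shift_px=0)
    roi = fit_roi(aligned.I, config)
    lm = detect_landmarks(aligned, roi, config)
    return aligned, roi, lm
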
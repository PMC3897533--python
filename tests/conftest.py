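"""Shared fixtures: plausible test parameters and one full calibration.

The full anchor calibration takes ~10 s, so it runs once per session;
tests that only exercise update arithmetic use a fixed plausible
(alpha, m_h) instead.
"""

import pytest

from streamweb import (
    CalibrationSpec,
    FoodWebState,
    ModelParams,
    calibrate_free_parameters,
)


@pytest.fixture
def params() -> ModelParams:
    """Field-derived rates with plausible (uncalibrated) alpha and m_h."""
    return ModelParams(alpha=1.5, m_h=0.04)


@pytest.fixture
def ref_state() -> FoodWebState:
    """Reference starting pools with a mid-range detritus stock."""
    return FoodWebState(A=1.59, D=40.0, H_alg=0.05, H_det=0.05,
                        G_alg=0.065, G_det=0.065, T=5.12, S=13.42)


@pytest.fixture(scope="session")
def calibration():
    """Full anchor calibration of (alpha, m_h, D_0) at default settings."""
    return calibrate_free_parameters(CalibrationSpec(), ModelParams())


@pytest.fixture(scope="session")
def fast_spec() -> CalibrationSpec:
    """Coarser search settings for calibration tests that rerun the fit."""
    return CalibrationSpec(grid_points=(7, 7), refine_sweeps=2,
                           refine_iters=12, bisect_iters=35)


@pytest.fixture(scope="session")
def contrasts(calibration):
    """Every reported scenario contrast at the calibrated parameters."""
    from streamweb import study_contrasts
    return study_contrasts(calibration.params, calibration.D_0)
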
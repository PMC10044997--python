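import numpy as np
import pytest

from retirr import synth
from retirr.containers import GAZES, IrregularitySpectrum, EyeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_contour():
    """Flat contour at 3 mm depth, 257 columns over 16 mm."""
    spec = synth.ContourSpec(n_cols=257, base_poly=(3.0, 0.0, 0.0))
    return synth.generate_contour(spec, seed=0, gaze="up")


def make_eye(eye_id="PVD-000", diagnosis="PVD", axial=24.4, age=65.0,
             bin_value=0.1, curvature=-0.01):
    """An EyeRecord with constant spectra across all four gazes."""
    spectra = {
        g: IrregularitySpectrum(
            bins=np.full(30, bin_value), curvature=curvature,
            signal_length_mm=16.0, gaze=g,
        )
        for g in GAZES
    }
    return EyeRecord(eye_id=eye_id, diagnosis=diagnosis, axial_length_mm=axial,
                     age_years=age, spectra=spectra)


@pytest.fixture
def constant_eye():
    return make_eye()
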
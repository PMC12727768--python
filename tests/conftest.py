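import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgvmd import (
    ClassifierSpec,
    FeatureMatrix,
    ProtocolSpec,
    bandpass_filter,
    cross_validate,
    extract_td8,
    extract_vmd_svd,
    make_synthetic_emg,
    notch_filter,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_recording():
    """Reduced-scale study conditions: 4 motions, 2 reps of 2-s contractions
    with 2-s rests, 3 channels at 2000 Hz, preprocessed with the standard
    band-pass + notch chain."""
    protocol = ProtocolSpec(n_reps=2, contraction_s=2.0, rest_s=2.0, seed=11)
    rec = make_synthetic_emg(protocol)
    return notch_filter(bandpass_filter(rec))


@pytest.fixture(scope="session")
def tiny_recording():
    """Minimal labelled recording for shape/dimensionality checks."""
    protocol = ProtocolSpec(n_reps=1, contraction_s=1.0, rest_s=0.5, seed=5)
    return make_synthetic_emg(protocol)


@pytest.fixture(scope="session")
def pipeline_features(reduced_recording):
    """VMD-SVD (K=6) and TD8 feature matrices from the reduced recording."""
    return {
        "vmd": extract_vmd_svd(reduced_recording, K=6),
        "td8": extract_td8(reduced_recording),
    }


@pytest.fixture(scope="session")
def pipeline_cv(pipeline_features):
    """Random-forest 10-fold results for both feature sets plus a
    label-shuffled null run."""
    spec = ClassifierSpec("RF")
    fv, ft = pipeline_features["vmd"], pipeline_features["td8"]
    rng = np.random.default_rng(0)
    shuffled = FeatureMatrix(
        fv.values, rng.permutation(fv.row_labels), fv.col_names, "shuffled"
    )
    return {
        "vmd": cross_validate(fv, spec, seed=0),
        "td8": cross_validate(ft, spec, seed=0),
        "shuffled": cross_validate(shuffled, spec, seed=0),
    }
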
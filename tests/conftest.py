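import numpy as np
import pytest

from covalkit import AnisotropyCalibration
from covalkit.synthesize import generate


@pytest.fixture
def calib():
    return AnisotropyCalibration(A_f=20.0, A_b=120.0)


@pytest.fixture
def write_dataset(tmp_path):
    """Generate a synthetic dataset and write its CSV; returns (path, truth)."""

    def _write(spec, name="data.csv"):
        df, truth = generate(spec)
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path, truth

    return _write


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # fits on deliberately noisy/edge-case data emit advisory warnings;
    # tests assert on results (and on warnings explicitly where relevant)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20231010)
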
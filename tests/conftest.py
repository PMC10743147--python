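import numpy as np
import pytest

from biososs import (
    BeamParams,
    DetectorParams,
    build_detector,
    generate_synthetic_ensemble,
)


@pytest.fixture(scope="session")
def baseline_beam():
    return BeamParams(energy_keV=12.0, photons=1e14, focal_size_nm=100.0)


@pytest.fixture(scope="session")
def baseline_det():
    return DetectorParams(n_pixels=250, pixel_size_um=234.0, distance_mm=40.0)


@pytest.fixture(scope="session")
def small_det_model(baseline_beam):
    """A 32x32 detector with baseline pitch/distance — fast but same dq."""
    return build_detector(baseline_beam, DetectorParams(32, 234.0, 40.0))


@pytest.fixture(scope="session")
def fit_det_model(baseline_beam):
    """A 128-pixel detector for retrieval tests."""
    return build_detector(baseline_beam, DetectorParams(128, 234.0, 40.0))


@pytest.fixture(scope="session")
def tiny_ensemble():
    """Ten-residue, three-snapshot synthetic ensemble."""
    return generate_synthetic_ensemble(n_residues=10, n_snapshots=3, seed=42)


@pytest.fixture(scope="session")
def rigid_conformer(tiny_ensemble):
    return tiny_ensemble[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
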
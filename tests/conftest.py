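import numpy as np
import pytest

import flexscan as fs


@pytest.fixture(scope="session")
def helix24():
    return fs.make_helix(24)


@pytest.fixture(scope="session")
def planted_ensemble_16(helix24):
    """16-conformer ensemble with a planted amplitude peak at residue 13."""
    amps = np.full(24, 0.3)
    amps[12] = 2.0
    spec = fs.FlexSpec(n_residues=24, amplitude_profile=amps, n_conformers=16, seed=1)
    return fs.make_flex_ensemble(helix24, spec), amps


@pytest.fixture(scope="session")
def planted_mode_trajectory(helix24):
    """10k-frame Gaussian trajectory with two planted modes (9 and 1 amu·Å²)."""
    v = fs.random_orthonormal_modes(24, 2, seed=5)
    spec = fs.ModeSpec(eigenvectors=v, variances=np.array([9.0, 1.0]),
                       n_frames=10_000, frame_interval=5.0, seed=5)
    return fs.make_mode_trajectory(helix24, spec), v
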
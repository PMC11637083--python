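import numpy as np
import pytest

import footclear as fc


@pytest.fixture(scope="session")
def shoe_cloud():
    return fc.make_shoe_cloud()


@pytest.fixture(scope="session")
def typical_bout(shoe_cloud):
    """Zero-noise 10-stride typical bout: (params, truth, recording)."""
    params = fc.scenario_params("typical", seed=42, n_strides=10)
    truth = fc.simulate_foot_poses(params, shoe_cloud)
    rec = fc.synthesize_imu(truth, params)
    return params, truth, rec


@pytest.fixture(scope="session")
def analyzed_typical(shoe_cloud, typical_bout):
    """Full pipeline result and oracle for the zero-noise typical bout."""
    _params, truth, rec = typical_bout
    bout = fc.analyze_bout(rec, shoe_cloud)
    oracle = fc.oracle_clearance(truth, shoe_cloud)
    return bout, oracle


def random_rotation(rng):
    v = rng.normal(size=3)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(v / np.linalg.norm(v) * rng.uniform(0, np.pi)).as_matrix()
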
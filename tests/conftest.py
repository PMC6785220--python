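import numpy as np
import pytest

from ecogwaves import synthetic


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid_8x8():
    return synthetic.GridGeometry.regular_grid(8, 8, 10.0)


@pytest.fixture(scope="session")
def grid_4x6():
    return synthetic.GridGeometry.regular_grid(4, 6, 10.0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One small simulated dataset shared by I/O and pipeline tests."""
    out = tmp_path_factory.mktemp("dataset")
    geom = synthetic.GridGeometry.regular_grid(4, 4, 10.0)
    spec = synthetic.TrialSpec(
        n_trials_per_session=10, n_sessions=2, trial_duration=2.0, baseline_duration=1.0
    )
    gt = synthetic.default_ground_truth(geom, seed=7)
    paths = synthetic.assemble_dataset(geom, spec, gt, out)
    return {"paths": paths, "geometry": geom, "trial_spec": spec, "ground_truth": gt}
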
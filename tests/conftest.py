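import numpy as np
import pytest

from poselie import (
    CalibrationSet,
    Compound,
    GeneratorSpec,
    LIEParams,
    PoseDescriptor,
    gen_energy_dataset,
)


@pytest.fixture
def single_pose_set():
    """Noiseless single-pose calibration set generated with alpha=0.5, beta=0.3."""
    spec = GeneratorSpec(n_compounds=20, poses_per_compound=1, seed=11)
    _, calib, truth = gen_energy_dataset(spec)
    return calib, truth


@pytest.fixture
def multi_pose_set():
    """Noiseless three-pose set whose dG_obs sit exactly at the weighted fixed point."""
    spec = GeneratorSpec(n_compounds=15, poses_per_compound=3, seed=13)
    _, calib, truth = gen_energy_dataset(spec)
    return calib, truth


@pytest.fixture
def tiny_set():
    """Hand-sized 4-compound single-pose set for oracle comparisons."""
    descriptors = [
        (-90.0, -25.0, -52.0),
        (-70.0, -40.0, -48.0),
        (-110.0, -10.0, -57.0),
        (-60.0, -55.0, -46.0),
    ]
    compounds = [
        Compound(f"c{i}", dg, [PoseDescriptor(f"c{i}", "p0", lj, cl)])
        for i, (lj, cl, dg) in enumerate(descriptors)
    ]
    return CalibrationSet(compounds)


def ols(x: np.ndarray, y: np.ndarray, intercept: bool = False) -> np.ndarray:
    """Independent ordinary-least-squares oracle."""
    a = np.column_stack([x, np.ones(len(x))]) if intercept else x
    return np.linalg.solve(a.T @ a, a.T @ y)
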
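"""Shared fixtures: phantoms at two resolutions and a toy separable split.

Session-scoped where construction is expensive; all randomness is seeded.
"""

import numpy as np
import pytest

from eitgesture import forward_model as fm
from eitgesture.synthetic_gestures import Dataset, DatasetSplit, GestureSample


@pytest.fixture(scope="session")
def fine_phantom() -> fm.ArmPhantom:
    return fm.default_phantom(mesh_h=fm.MESH_H_FINE)


@pytest.fixture(scope="session")
def coarse_phantom() -> fm.ArmPhantom:
    return fm.default_phantom(mesh_h=fm.MESH_H_COARSE)


@pytest.fixture(scope="session")
def disk_phantom() -> fm.ArmPhantom:
    """Homogeneous unit disk with narrow (near point-like) electrodes."""
    return fm.build_phantom(
        outer=fm.Ellipse(0.0, 0.0, 1.0, 1.0), bones=(),
        sigma_muscle=1.0, sigma_bone=1.0, mesh_h=0.05, electrode_width=0.02,
    )


def _toy_samples(templates: np.ndarray, n_per: int, seed: int, noise: float = 0.01):
    r = np.random.default_rng(seed)
    out = []
    for c in range(len(templates)):
        for _ in range(n_per):
            v = np.clip(templates[c] * (1 + noise * r.standard_normal(40)), 0, None)
            out.append(GestureSample(voltages=v, label=c, iteration=seed))
    return tuple(out)


@pytest.fixture(scope="session")
def toy_model(toy_split):
    """A CG-SVM trained on the toy split (shared across test modules)."""
    from eitgesture.cgsvm_model import CGSVMConfig, train

    return train(toy_split, CGSVMConfig(n_classes=4, epochs=50, seed=1))


@pytest.fixture(scope="session")
def toy_split() -> DatasetSplit:
    """Four well-separated 40-vector template classes with 1% noise."""
    rng = np.random.default_rng(0)
    templates = rng.uniform(0.5, 1.5, size=(4, 40)) * 1e-3
    return DatasetSplit(
        train=Dataset(_toy_samples(templates, 50, 0), "toy"),
        test=Dataset(_toy_samples(templates, 20, 1), "toy"),
    )
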
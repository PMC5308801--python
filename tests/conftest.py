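"""Shared fixtures: random SPD matrices, tiny trials, and small datasets."""

from __future__ import annotations

import numpy as np
import pytest

from posturekit.datamodel_io import Device, JointSubset, Trial
from posturekit.synthetic_data import SyntheticConfig, generate_dataset


def random_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """Random SPD matrix with eigenvalues log-uniform in [1/cond, cond]."""
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = np.exp(rng.uniform(-np.log(cond), np.log(cond), size=n))
    return (q * w) @ q.T


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def mk2_trial(rng) -> Trial:
    """A 16-joint (48-channel) MK2 trial of 100 frames."""
    return Trial(
        subject_id="S01",
        task_id=1,
        condition_id=1,
        device=Device.MK2,
        channel_labels=tuple(JointSubset.UPPER_16.channel_labels),
        sample_rate_hz=30.0,
        samples=rng.standard_normal((48, 100)),
    )


@pytest.fixture
def full25_trial(rng) -> Trial:
    return Trial(
        subject_id="S01",
        task_id=1,
        condition_id=1,
        device=Device.MK2,
        channel_labels=tuple(JointSubset.FULL_25.channel_labels),
        sample_rate_hz=30.0,
        samples=rng.standard_normal((75, 60)),
    )


@pytest.fixture
def kfp_trial(rng) -> Trial:
    return Trial(
        subject_id="S01",
        task_id=1,
        condition_id=1,
        device=Device.KFP,
        channel_labels=("cop_x", "cop_y"),
        sample_rate_hz=600.0,
        samples=rng.standard_normal((2, 2000)),
    )


@pytest.fixture(scope="session")
def small_dataset():
    """4 subjects x 6 tasks x 3 conditions, paired devices -- fast fixture."""
    return generate_dataset(SyntheticConfig(n_subjects=4, frames=200, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The full default study layout (12 x 6 x 3, paired)."""
    return generate_dataset(SyntheticConfig(seed=11))
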
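"""Shared fixtures: synthetic actors, trials and feature tables.

Everything is generated programmatically; session scope keeps the heavier
tables (built once) shared across test modules.
"""

import logging

import numpy as np
import pytest

from vitalkin.features import build_table
from vitalkin.io import TrialMeta, TrialRecording
from vitalkin.kinematics import KinematicSignals, SegmentedTrial
from vitalkin.synthetic import (
    ACTIONS,
    CONDITIONS,
    ActorProfile,
    SynthClassParams,
    SynthDatasetConfig,
    TrialSpec,
    generate_dataset,
    generate_trial,
)

logging.getLogger("vitalkin").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def long_arm_actor():
    """An actor with enough reach that arbitrary oracle end points are valid."""
    return ActorProfile("oracle", "m", 0.9, 0.85, np.array([0.0, -0.6, 0.3]), 0.2, 0.03)


def make_straight_trial(D=0.5, T=1.0, actor=None, seed=1, fps=100.0, **params):
    """Noiseless minimum-jerk trial along +y of chord length D, duration T."""
    if actor is None:
        actor = ActorProfile("oracle", "m", 0.9, 0.85, np.array([0.0, -0.6, 0.3]), 0.2, 0.03)
    spec = TrialSpec(
        actor=actor,
        action="grasp",
        condition="neutral",
        fps=fps,
        start_point=np.array([0.0, 0.0, 0.0]),
        end_point=np.array([0.0, D, 0.0]),
    )
    return generate_trial(SynthClassParams(duration_s=T, **params), spec, seed)


@pytest.fixture(scope="session")
def straight_trial():
    return make_straight_trial()


def make_path_fixture(pos, dt=0.01):
    """Wrap a raw wrist path into (recording, signals, full-span segmentation).

    Derivatives are plain central differences (no filtering) so closed-form
    path oracles apply exactly.
    """
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    time = np.arange(n) * dt
    vel = np.gradient(pos, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    jerk = np.gradient(acc, dt, axis=0)
    drift = np.outer(np.linspace(0, 0.01, n), [0.0, 1.0, 0.0])  # shoulder sway
    rec = TrialRecording(
        time=time,
        points={
            "C1": pos,
            "C2": pos * 0 + [0.1, 0.0, 0.0],
            "C3": pos * 0 + [0.2, 0.0, 0.0] + drift,
            "C4": pos * 0 + [0.2, -0.1, 0.0],
        },
        meta=TrialMeta("fix", "a", "grasp", "neutral"),
    )
    sig = KinematicSignals(
        pos=pos,
        vel=vel,
        acc=acc,
        jerk=jerk,
        speed=np.linalg.norm(vel, axis=1),
        accel_mag=np.linalg.norm(acc, axis=1),
        jerk_mag=np.linalg.norm(jerk, axis=1),
        dt=dt,
    )
    seg = SegmentedTrial(go_range=(0, n), return_range=(n, n), n_samples=n)
    return rec, sig, seg


@pytest.fixture(scope="session")
def mini_table():
    """105-trial feature table (3 per action x condition cell)."""
    counts = {a: {c: 3 for c in CONDITIONS} for a in ACTIONS}
    table, discards = build_table(generate_dataset(SynthDatasetConfig(counts=counts, seed=0)))
    assert len(discards) == 0
    return table


@pytest.fixture(scope="session")
def table700():
    """700-trial feature table (20 per cell): the default study conditions."""
    counts = {a: {c: 20 for c in CONDITIONS} for a in ACTIONS}
    table, _ = build_table(generate_dataset(SynthDatasetConfig(counts=counts, seed=11)))
    return table


@pytest.fixture(scope="session")
def table_reference_scaled():
    """Feature table with the reference campaign's class proportions at ~1/5 size."""
    from vitalkin.synthetic import REFERENCE_COUNTS

    counts = {a: {c: max(1, n // 5) for c, n in cs.items()} for a, cs in REFERENCE_COUNTS.items()}
    table, _ = build_table(generate_dataset(SynthDatasetConfig(counts=counts, seed=3)))
    return table
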
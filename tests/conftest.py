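"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import semgbench as sb
from semgbench.core import ConditionKey, DatasetRegistry


def generate_conditions(
    subjects,
    keys,
    n_groups: int,
    seed: int,
    shift=None,
    config_kwargs=None,
) -> DatasetRegistry:
    """Generate only the requested (day, fatigue, angle) keys."""
    config = sb.GeneratorConfig(seed=seed, n_groups=n_groups, **(config_kwargs or {}))
    shift = shift or sb.ConditionShift()
    profiles = sb.default_profiles(config.separation)
    registry = DatasetRegistry()
    for subject in subjects:
        for key in keys:
            for group in range(1, n_groups + 1):
                for gesture in config.gestures:
                    registry.add(
                        sb.generate_recording(
                            subject, gesture, key, group, config, shift, profiles
                        )
                    )
    return registry


@pytest.fixture(scope="session")
def study_features():
    """Feature table of a full 18-condition study: 1 subject, 4 groups,
    default condition shifts. Shared read-only across tests."""
    subjects = sb.make_subjects(1, seed=5)
    config = sb.GeneratorConfig(n_groups=4, seed=5)
    registry = sb.generate_study(subjects, config)
    return sb.featurize_registry(registry)


@pytest.fixture(scope="session")
def gaussian_task():
    """Two spherical Gaussian classes separated by 6 sd: 500/500 split."""
    rng = np.random.default_rng(42)
    d = 16
    mu = np.zeros(d)
    mu2 = np.zeros(d)
    mu2[0] = 6.0
    X_train = np.vstack(
        [rng.normal(mu, 1.0, (500, d)), rng.normal(mu2, 1.0, (500, d))]
    )
    y_train = np.array(["c0"] * 500 + ["c1"] * 500)
    X_test = np.vstack(
        [rng.normal(mu, 1.0, (500, d)), rng.normal(mu2, 1.0, (500, d))]
    )
    y_test = np.array(["c0"] * 500 + ["c1"] * 500)
    return X_train, y_train, X_test, y_test
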
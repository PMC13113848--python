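"""Shared fixtures: reduced desk-scale arrays and simulated acquisitions.

Everything is generated programmatically and seeded; session scope keeps the
simulator cost paid once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import flexbeam as fb


@pytest.fixture(scope="session")
def desk_spec():
    """16-element, 464-sample reduced array (full pitch/frequency/sampling)."""
    return fb.desk_spec()


@pytest.fixture(scope="session")
def desk_phantom():
    """Point-target layout scaled to the desk array's ~5.7 mm field of view."""
    return fb.cirs_like_phantom(max_depth=4.5, lateral_span=8.0)


@pytest.fixture(scope="session")
def desk_rf(desk_spec, desk_phantom):
    """One noiseless flat desk-scale acquisition."""
    acq = fb.AcquisitionConfig(voltage_gain=1.0, noise_sigma=0.0, seed=1)
    return fb.simulate_acquisition(desk_phantom, desk_spec, fb.ArrayShape.flat(), acq)


@pytest.fixture(scope="session")
def desk_grid(desk_spec):
    """128-point focal grid spanning the desk recording window."""
    return fb.default_focal_grid(desk_spec, 128)


@pytest.fixture(scope="session")
def desk_pairs(desk_spec, desk_phantom, desk_grid):
    """Tiny paired dataset: 1 experiment, 3 acquisitions, radii 300/550/800."""
    acq = fb.AcquisitionConfig(voltage_gain=30.0, noise_sigma=0.002, seed=11)
    series = fb.emulate_experiment_series(desk_phantom, desk_spec, 3, acq, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            fb.curvature_sweep(
                rf, 300.0, 800.0, 250.0, desk_spec, desk_grid,
                meta={"experiment_id": 1, "acquisition_id": a, "voltage": 30.0},
            )
            for a, rf in enumerate(series, start=1)
        ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dnpad_smoke(desk_pairs):
    """One 30-epoch desk-scale training run (no injected noise), shared by the
    training-behavior tests: 2 acquisitions train, 1 held out for testing."""
    from flexbeam.dataset import DatasetSplit
    from flexbeam.dnpad import (
        DiscriminatorConfig,
        DNPADModel,
        GeneratorConfig,
        TrainConfig,
    )

    split = DatasetSplit(desk_pairs[0] + desk_pairs[1], [], desk_pairs[2])
    model = DNPADModel(
        split,
        GeneratorConfig(base_channels=4),
        DiscriminatorConfig(base_channels=4),
        TrainConfig(epochs=30, seed=100),
    )
    return model.fit()
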
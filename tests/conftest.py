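import logging
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from synaptomap.pipeline import (  # noqa: E402
    RunConfig,
    assemble_field,
    compute_thresholds,
    process_field,
)
from synaptomap.synthetic_data import SynthConfig, generate_field  # noqa: E402

logging.getLogger("synaptomap").setLevel(logging.ERROR)


def noise_free(**overrides) -> SynthConfig:
    """Config with every corruption (noise, gradient, shift, offset) off."""
    kw = dict(
        poisson_scale=0.0,
        gaussian_noise_sd=0.0,
        illumination_gradient_amplitude=0.0,
        shift_range_px=0,
        background_level=0.0,
        decoy_rate=0.0,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


@pytest.fixture(scope="session")
def default_field():
    """One default-noise field plus its ground truth."""
    config = SynthConfig(image_shape=(256, 256), seed=42)
    mfield, truth = generate_field(config, 0, 0)
    return config, mfield, truth


@pytest.fixture(scope="session")
def processed_default_field(default_field):
    _, mfield, truth = default_field
    run_config = RunConfig()
    proc = process_field(mfield, run_config)
    return proc, truth, run_config


@pytest.fixture(scope="session")
def assembled_default_field(processed_default_field):
    proc, truth, run_config = processed_default_field
    thresholds = compute_thresholds([proc], run_config)
    synapses, counts = assemble_field(proc, thresholds, run_config)
    return proc, truth, synapses, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_region(rng, max_extent=9, p_fill=0.55):
    """A random connected-ish pixel region inside a small window."""
    h = int(rng.integers(2, max_extent))
    w = int(rng.integers(2, max_extent))
    mask = rng.random((h, w)) < p_fill
    if not mask.any():
        mask[rng.integers(h), rng.integers(w)] = True
    rows, cols = np.nonzero(mask)
    return rows + 2, cols + 2
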
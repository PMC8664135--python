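import logging

import numpy as np
import pytest

from petqa.localize import ROISample, ROISpec
from petqa.simulate import AcquisitionConfig, PhantomGeometry, simulate_phantom

logging.getLogger("petqa").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def fast_config():
    """Small, fast acquisition used where full realism is not needed."""
    return AcquisitionConfig(n_slices=8, seed=123)


@pytest.fixture(scope="session")
def sim_phantom(geometry, fast_config):
    """One default simulated phantom with ground truth."""
    return simulate_phantom(geometry, fast_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return AcquisitionConfig(
        n_slices=4, noise_rel_sd=0.0, nonuniformity_rms=0.0, seed=1
    )


@pytest.fixture(scope="session")
def noiseless_phantom(geometry, noiseless_config):
    return simulate_phantom(geometry, noiseless_config)


def make_sample(values, offsets=None, pixel_size_mm=3.8, label="hot-8", manual=False):
    """Build an ROISample directly from values (+ optional offsets)."""
    values = np.asarray(values, dtype=float)
    if offsets is None:
        # lay pixels on a line through the center
        n = len(values)
        offsets = np.stack([np.zeros(n), np.arange(n) - (n - 1) / 2.0], axis=1)
    spec = ROISpec(center=(0.0, 0.0), label=label, manually_placed=manual)
    return ROISample(
        spec=spec, values=values, offsets=np.asarray(offsets, float),
        pixel_size_mm=pixel_size_mm,
    )


def disc_sample(radius_px=5.26, rng=None, base=42.0, sd=4.2, label="background"):
    """A circular ROI sample on the integer grid, optionally with noise."""
    r = int(np.ceil(radius_px))
    rows, cols = np.mgrid[-r : r + 1, -r : r + 1]
    mask = rows**2 + cols**2 < radius_px**2
    offsets = np.stack([rows[mask], cols[mask]], axis=1).astype(float)
    n = len(offsets)
    values = np.full(n, base)
    if rng is not None:
        values = values + rng.standard_normal(n) * sd
    spec = ROISpec(center=(0.0, 0.0), label=label)
    return ROISample(spec=spec, values=values, offsets=offsets, pixel_size_mm=3.8)
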
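"""Shared fixtures: small phantoms reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import discquant as dq


@pytest.fixture(scope="session")
def small_phantom_spec() -> dq.PhantomSpec:
    return dq.PhantomSpec(a=20.0, b=15.0, h=10.0, spacing=(0.5, 0.5, 0.5))


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec) -> dq.LabelVolume:
    return dq.gen_disc_volume(small_phantom_spec)


@pytest.fixture(scope="session")
def shaver_phantom(small_phantom) -> dq.LabelVolume:
    cav = dq.CavitySpec(technique="shaver", target_volume_mm3=350.0)
    return dq.carve_cavity(small_phantom, cav, seed=11)


@pytest.fixture(scope="session")
def laser_phantom(small_phantom) -> dq.LabelVolume:
    cav = dq.CavitySpec(technique="laser", target_volume_mm3=None)
    return dq.carve_cavity(small_phantom, cav, seed=12)


@pytest.fixture(scope="session")
def bean_phantom() -> dq.LabelVolume:
    """Asymmetric bean outline: posterior concavity off the midline."""
    spec = dq.PhantomSpec(
        a=20.0,
        b=15.0,
        h=10.0,
        spacing=(0.5, 0.5, 0.5),
        concavity_depth=2.5,
        concavity_radius=8.0,
        concavity_offset=3.0,
    )
    return dq.gen_disc_volume(spec)


def circle_mask(radius_mm: float, spacing: float) -> np.ndarray:
    n = int(2 * radius_mm / spacing) + 5
    xs = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    return X**2 + Y**2 <= radius_mm**2
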
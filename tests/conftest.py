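"""Shared phantom fixtures.

Session-scoped bundles are treated as read-only by every test.
"""

import pytest

from callusmri.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_bundle():
    """Noise-free, gradient-free day-10 phantom (MRI grid only), artifacts on."""
    spec = PhantomSpec(
        healing_day=10, noise_sigma=0.0, coil_gradient_amplitude=0.0, seed=11
    )
    return generate_phantom(spec, modalities=("mri",))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default-condition day-14 phantom (5% Rician noise, 10% coil ramp)."""
    spec = PhantomSpec(healing_day=14, seed=23)
    return generate_phantom(spec, modalities=("mri",))


@pytest.fixture(scope="session")
def full_bundle():
    """Default day-10 phantom with all modalities (8 μm μCT, histology)."""
    spec = PhantomSpec(healing_day=10, seed=5)
    return generate_phantom(spec)


def small_spec(**overrides) -> PhantomSpec:
    """A reduced-geometry spec for fast multi-modality runs."""
    kwargs = dict(
        healing_day=10,
        cortex_outer_radius=500.0,
        cortex_thickness=150.0,
        gap_width=400.0,
        callus_max_radius=1000.0,
        pin_positions=(438.0, 838.0, 2438.0, 2838.0),
        mri_shape=(64, 64, 12),
        uct_spacing=(16.0, 16.0, 16.0),
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
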
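"""Shared fixtures: small ground-truthed scenes generated at test time."""

from dataclasses import replace

import pytest

from rbcagg import RunConfig, SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_spec():
    """A compact, quick-to-render field with the default morphology mix."""
    return SceneSpec(field_width_px=400, field_height_px=200, areal_density=0.10, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


@pytest.fixture(scope="session")
def noisy_spec(small_spec):
    return replace(small_spec, noise_sd=25.5, illumination_gradient=0.3, seed=43)


@pytest.fixture(scope="session")
def pixel_exact_config():
    """Pipeline settings that preserve masks pixel-exactly on clean images."""
    return RunConfig(illumination_correction=False, median_size=0, fill_holes=False)
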
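"""Shared fixtures: desk-scale constraints and small rendered stimuli."""

import numpy as np
import pytest

from bosbench import stimgen


@pytest.fixture(scope="session")
def c64():
    return stimgen.GeometryConstraints.at_scale(64)


@pytest.fixture(scope="session")
def c227():
    return stimgen.GeometryConstraints()


@pytest.fixture(scope="session")
def contour_specs(c64):
    """A bank of valid contour rectangle specs at desk scale."""
    return [stimgen.sample_stimulus(c64, "contour", "rectangle", seed)
            for seed in range(40)]


@pytest.fixture(scope="session")
def contour_images(contour_specs):
    return [stimgen.render_contour(s) for s in contour_specs]
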
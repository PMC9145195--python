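"""Shared small fixtures: tiny templates and models built programmatically."""

import numpy as np
import pytest

from cellstretch import MaterialParams, TemplateSpec
from cellstretch.solver import FemModel
from cellstretch.template import (extrude_template, flat_sheet, make_cell_grid,
                                  smooth_template)


def tiny_spec(**kw) -> TemplateSpec:
    """Coarse, small template spec used across the unit tests."""
    defaults = dict(aspect_ratio=1, template_extent=(20.0, 20.0),
                    vertex_spacing=5.0, extrusion_segments=3,
                    segment_length=20.0 / 3.0, smoothing_iterations=0)
    defaults.update(kw)
    return TemplateSpec(**defaults)


@pytest.fixture(scope="session")
def single_cell():
    """One unsmoothed 20 µm cubic cell."""
    return extrude_template(make_cell_grid(tiny_spec()))


@pytest.fixture(scope="session")
def two_cells():
    """Two adjacent unsmoothed cells sharing one band wall."""
    return extrude_template(make_cell_grid(
        tiny_spec(template_extent=(40.0, 20.0))))


@pytest.fixture(scope="session")
def small_tissue():
    """3x3 smoothed square-cell tissue (staggered off)."""
    spec = tiny_spec(template_extent=(60.0, 60.0), staggered=False,
                     smoothing_iterations=2)
    return smooth_template(extrude_template(make_cell_grid(spec)))


@pytest.fixture(scope="session")
def sheet():
    return flat_sheet(width=60.0, height=30.0, spacing=10.0, thickness=1.0)


@pytest.fixture()
def iso_material():
    return MaterialParams.isotropic(100.0, 0.0)


@pytest.fixture()
def two_cell_model(two_cells, iso_material):
    return FemModel(two_cells, iso_material)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
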
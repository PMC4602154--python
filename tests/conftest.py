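"""Shared phantom fixtures.

All fixtures are generated programmatically; session scope keeps the more
expensive voxel phantoms to a single construction.
"""

import numpy as np
import pytest

from trabgeo import (
    make_cylinder,
    make_lattice,
    make_plate,
    make_pseudo_trabecular,
    make_sphere,
)

# the phantom-validation meshing protocol: block resampling by 3 provides the
# grayscale anti-aliasing that lets marching cubes reconstruct smooth analytic
# surfaces; no additional Laplacian smoothing, which would shrink thin rods
VALIDATION_MESH = dict(resample_factor=3, smoothing=0.0)


@pytest.fixture(scope="session")
def sphere40():
    return make_sphere(40, (100, 100, 100))


@pytest.fixture(scope="session")
def sphere20():
    return make_sphere(20, (52, 52, 52))


@pytest.fixture(scope="session")
def cylinder10():
    return make_cylinder(10, (128, 64, 64), axis=0)


@pytest.fixture(scope="session")
def plate8():
    return make_plate(8, (64, 128, 128), normal_axis=0)


@pytest.fixture(scope="session")
def lattice_mixed():
    return make_lattice(rod_radius=5, plate_thickness=6, cell_spacing=24, dims=(72, 72, 72))


@pytest.fixture(scope="session")
def pseudo_small():
    """A small trabecular-like field for pipeline tests (not the resorption substrate)."""
    return make_pseudo_trabecular(dims=(64, 64, 64), target_bvtv=0.35, correlation_length=7, seed=3)
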
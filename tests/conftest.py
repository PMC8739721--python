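"""Shared fixtures.

Registration on 64^3 phantoms costs seconds, so the default case and its
recovered transforms are computed once per session and shared by the
registration, validation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from rebed.geometry import GridGeometry
from rebed.phantom import PhantomSpec, make_case
from rebed.registration import deformable_register, rigid_register


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(2.5, 2.5, 2.5), dims=(8, 8, 8))


@pytest.fixture(scope="session")
def default_case():
    """The standard two-course phantom: 50 Gy/4 fx + 70 Gy/10 fx, 4 mm
    sinusoidal deformation, small rigid offset."""
    return make_case(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def recovered(default_case):
    """Rigid + deformable registration recovered from the default case."""
    rigid = rigid_register(default_case.reference.anatomy, default_case.moving.anatomy)
    field = deformable_register(default_case.reference.anatomy,
                                default_case.moving.anatomy, init=rigid)
    return rigid, field


@pytest.fixture(scope="session")
def rigid_only_case():
    """A phantom with a known pure rigid offset and no deformation."""
    return make_case(PhantomSpec(deformation_amplitude_mm=0.0,
                                 rigid_translation_mm=(5.0, -3.0, 2.0),
                                 rigid_rotation_deg=0.0))


@pytest.fixture(scope="session")
def rotation_only_case():
    return make_case(PhantomSpec(deformation_amplitude_mm=0.0,
                                 rigid_translation_mm=(0.0, 0.0, 0.0),
                                 rigid_rotation_deg=5.0))


@pytest.fixture(scope="session")
def identity_case():
    """moving == reference (no rigid offset, no deformation)."""
    return make_case(PhantomSpec(deformation_amplitude_mm=0.0,
                                 rigid_translation_mm=(0.0, 0.0, 0.0),
                                 rigid_rotation_deg=0.0))


def body_region(case) -> np.ndarray:
    """Voxels carrying anatomical signal (inside the soft-tissue body)."""
    return case.reference.anatomy.values > -500.0
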
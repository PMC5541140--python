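"""Shared fixtures: all test data is generated programmatically at run time."""

from __future__ import annotations

import numpy as np
import pytest

from admtp.config import RunConfig
from admtp.geometry import ScalarField
from admtp.phantom import PhantomSpec, VesselTube, generate_phantom
from admtp.pipeline import Electrode, PlanningInputs


def small_spec() -> PhantomSpec:
    """Scaled-down head (2 mm voxels, same world geometry) for fast tests."""
    return PhantomSpec(grid_shape=(88, 88, 88),
                       spacing=(2.0, 2.0, 2.0)).with_default_corridors()


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_inputs(small_phantom):
    ph = small_phantom
    electrodes = [Electrode(e["id"], e["deep_roi_label"],
                            e["superficial_roi_label"], e["prior"])
                  for e in ph.strategy]
    return PlanningInputs(ph.parcellation, ph.arteries, ph.veins, ph.sulci,
                          ph.gm, ph.skull, electrodes)


@pytest.fixture()
def unit_grid():
    """Empty 32^3 field with 1 mm isotropic voxels, origin at the corner."""
    return ScalarField(np.zeros((32, 32, 32)), np.eye(4), "unit_grid")


def straight_vessel_spec(radius: float = 1.5) -> PhantomSpec:
    """A phantom holding a single straight vessel tube along z at x=y=0."""
    tube = VesselTube(points=((0.0, 0.0, -30.0), (0.0, 0.0, 30.0)),
                      radius=radius, kind="vein")
    return PhantomSpec(grid_shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0),
                       rois=(), vessels=(tube,), sulci=(), corridors=())


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
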
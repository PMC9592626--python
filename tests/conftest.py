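"""Shared fixtures: study parameters and cached FEM solves.

The expensive objects (solved pressure fields and their summaries) are
session-scoped so the solver runs once per configuration for the whole
suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonowell as sw


@pytest.fixture(scope="session")
def study() -> sw.FixtureSet:
    """Canonical study conditions: three drives, water medium, well geometry."""
    return sw.fixtures()


@pytest.fixture(scope="session")
def acoustics(study) -> sw.DerivedAcoustics:
    return sw.complex_acoustics(study.medium, study.drives[0].frequency)


@pytest.fixture(scope="session")
def fields_ref1(study) -> dict[float, sw.PressureField]:
    """Solved fields at the three drive powers, lambda/8 quadratic mesh."""
    powers = (0.30, 0.45, 0.60)
    return {
        p: sw.simulate(
            drive, medium=study.medium, geometry=study.geometry,
            config=sw.SolverConfig(refinement=1.0),
        )
        for p, drive in zip(powers, study.drives)
    }


@pytest.fixture(scope="session")
def summaries_ref1(study, fields_ref1) -> dict[float, sw.FieldSummary]:
    """Plane-average summaries of the three solved fields."""
    return {
        p: sw.summarize(f, sw.intensity(f), study.geometry)
        for p, f in fields_ref1.items()
    }


@pytest.fixture(scope="session")
def field_ref2(study) -> sw.PressureField:
    """Refined (lambda/16) quadratic solve at 0.45 W/cm^2, physical walls."""
    return sw.simulate(
        study.drives[1], medium=study.medium, geometry=study.geometry,
        config=sw.SolverConfig(refinement=2.0),
    )


@pytest.fixture(scope="session")
def rigid_fields(study) -> dict[float, sw.PressureField]:
    """Sound-hard-lateral solves (radially uniform configuration) at 0.45
    W/cm^2 for refinements 1 and 2, quadratic elements."""
    out = {}
    for refn in (1.0, 2.0):
        cfg = sw.SolverConfig(refinement=refn, lateral_condition="rigid")
        out[refn] = sw.simulate(
            study.drives[1], medium=study.medium, geometry=study.geometry, config=cfg
        )
    return out


@pytest.fixture(scope="session")
def validation_field(study) -> sw.PressureField:
    """The validation discretization: refinement 2, cubic elements,
    sound-hard lateral wall (the 1-D-column-equivalent configuration)."""
    cfg = sw.SolverConfig(refinement=2.0, lateral_condition="rigid", element_order=3)
    return sw.simulate(
        study.drives[1], medium=study.medium, geometry=study.geometry, config=cfg
    )


@pytest.fixture(scope="session")
def column_air(study, acoustics) -> sw.Column1D:
    """Analytic 1-D column with the air-impedance top at 0.45 W/cm^2."""
    return sw.analytic_1d_column(
        acoustics, study.drives[1], 4.017e2, study.geometry.solution_height
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
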
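"""Shared fixtures: templates, mode bases, and a small study population.

Everything is generated programmatically and deterministically; session
scope keeps the expensive template fits out of individual tests.
"""

import numpy as np
import pytest

import craniofit as cf
from craniofit import synthetic_anatomy as sa


@pytest.fixture(scope="session")
def templates2():
    return sa.make_template_pair(subdivisions=2)


@pytest.fixture(scope="session")
def templates3():
    return sa.make_template_pair(subdivisions=3)


@pytest.fixture(scope="session")
def basis2(templates2):
    return sa.make_mode_basis(templates2, 3)


@pytest.fixture(scope="session")
def subject2(templates2, basis2):
    """One representative in-population subject on the coarse template."""
    return sa.make_subject(
        templates2, basis2, np.array([4.0, -2.5, 1.5]), seed=7
    )


@pytest.fixture(scope="session")
def population2(templates2):
    """Small coarse-template population for model-building tests."""
    spec = cf.PopulationSpec(n_subjects=6, rank=3, seed=42)
    return spec, cf.make_population(spec, templates2)


@pytest.fixture(scope="session")
def models2(templates2, population2):
    """Skull/head/thickness models built from the coarse population."""
    _, pop = population2
    fitted_skulls = cf.fit_skull_population(
        templates2.skull, [s.skull_surface for s in pop], cf.FitSchedule(seed=0)
    )
    scans = [s.skin_surface.as_pointset() for s in pop]
    lmp = [
        {k: s.skin_surface.vertices[i] for k, i in templates2.head.landmarks.items()}
        for s in pop
    ]
    fitted_heads = cf.fit_head_population(
        templates2.head, scans, lmp, cf.FitSchedule(seed=0)
    )
    statistic, per_subject = cf.build_fstt_statistic(
        fitted_skulls, [s.skin_surface for s in pop]
    )
    return {
        "fitted_skulls": fitted_skulls,
        "fitted_heads": fitted_heads,
        "skull_model": cf.build_skull_model(fitted_skulls),
        "head_model": cf.build_head_model(fitted_heads),
        "statistic": statistic,
        "per_subject": per_subject,
        "fstt_model": cf.build_fstt_model(
            [d for d, _ in per_subject], [m for _, m in per_subject]
        ),
    }


@pytest.fixture(scope="session")
def config2(templates2):
    return cf.ReconstructionConfig(
        skull_template=templates2.skull, head_template=templates2.head, seed=0
    )
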
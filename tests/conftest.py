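"""Shared fixtures.

Expensive fits are session-scoped so the whole suite reuses them; every
stochastic fixture is seeded, so runs are reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

np.seterr(over="ignore", invalid="ignore", divide="ignore", under="ignore")

from poptk import (
    fit,
    generate_rich_recovery_set,
    generate_study,
    reference_model,
)
from poptk.pkmodel import DoseEvent, StructuralParams

TABLE_PARAMS = StructuralParams(cl=1.31, v1=9.84, q2=197.0, v2=39.1, q3=0.6, v3=9.01)
STUDY_DOSE = [DoseEvent(0.0, 1.0 / 6.0, 25.0)]


@pytest.fixture(scope="session")
def truth():
    return reference_model()


@pytest.fixture(scope="session")
def study20(truth):
    """A virtual study at the trial's own design (20 subjects)."""
    return generate_study(truth, seed=11)


@pytest.fixture(scope="session")
def fit20(truth, study20):
    """Self-simulated 20-subject study fitted from the generating values."""
    res = fit(study20.dataset, truth)
    assert res.converged
    return res


@pytest.fixture(scope="session")
def rich50(truth):
    return generate_rich_recovery_set(truth, 50, seed=1)


@pytest.fixture(scope="session")
def recovery_fits(truth):
    """Twenty replicate recovery fits of 50-subject rich studies.

    Each study is generated at the published final model and refitted
    starting from the generating values; used by the bias and recovery
    checks.  Returns a list of (natural-parameter dict, FitResult).
    """
    out = []
    for seed in range(1, 21):
        study = generate_rich_recovery_set(truth, 50, seed=seed)
        res = fit(study.dataset, truth, gtol=5e-3, max_outer_iter=300)
        out.append((res._packer.natural_params(res.model), res))
    return out
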
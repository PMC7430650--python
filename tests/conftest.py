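"""Shared fixtures: reference parameter sets, experimental designs and
(session-cached) noiseless global fits used by several test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ires40s.estimation import fit_pipeline
from ires40s.reaction_model import RateConstants
from ires40s.synthetic_data import (
    NoiseModel,
    generate_dataset,
    paper_design_suite,
    reference_parameters,
)

warnings.filterwarnings("ignore", message=".*best constrained.*")


@pytest.fixture(scope="session")
def wt() -> RateConstants:
    return reference_parameters("WT")


@pytest.fixture(scope="session")
def r68a() -> RateConstants:
    return reference_parameters("R68A")


@pytest.fixture(scope="session")
def design_suite():
    return paper_design_suite()


@pytest.fixture(scope="session")
def wt_noiseless(wt, design_suite):
    """Noiseless WT time courses at the four canonical designs."""
    return generate_dataset(wt, design_suite, NoiseModel(sigma=0.0, replicates=1, seed=0))


@pytest.fixture(scope="session")
def r68a_noiseless(r68a, design_suite):
    return generate_dataset(r68a, design_suite, NoiseModel(sigma=0.0, replicates=1, seed=0))


@pytest.fixture(scope="session")
def wt_fit(wt_noiseless):
    """Global two-step fit of the noiseless WT suite (expensive; shared)."""
    result, _ = fit_pipeline(wt_noiseless)
    return result


@pytest.fixture(scope="session")
def r68a_fit(r68a_noiseless):
    result, _ = fit_pipeline(r68a_noiseless)
    return result


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
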
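"""Shared fixtures: synthetic study conditions, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import polconvoy as pc
from polconvoy.simulate import EnergyLandscape


@pytest.fixture(scope="session")
def unit_spec():
    return pc.SyntheticUnitSpec()


@pytest.fixture(scope="session")
def hairpin_unit(unit_spec):
    return pc.gen_hairpin_unit(unit_spec)


@pytest.fixture(scope="session")
def surrogate_conditions():
    """Sequence, planted truth and sawtooth-surrogate landscape (7 kb)."""
    return pc.study_landscape()


@pytest.fixture(scope="session")
def computed_conditions():
    """Sequence, truth and builtin-backend folding landscape (7 kb)."""
    return pc.computed_landscape()


@pytest.fixture(scope="session")
def small_flat_landscape():
    return EnergyLandscape.flat(2000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
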
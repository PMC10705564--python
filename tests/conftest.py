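"""Shared fixtures: synthetic complexes and desk-scale sampler configs."""

from __future__ import annotations

import numpy as np
import pytest

from glowives.sampling import SamplerConfig, SearchBox
from glowives.scoring import ScoringParams
from glowives.synthetic import (CrossDockSpec, ToyComplexSpec, make_clash_fixture,
                                make_cross_dock_case, make_toy_complex)


@pytest.fixture(scope="session")
def holo_complex():
    """Clash-free pseudo-receptor complex (receptor, ligand, reference pose)."""
    return make_toy_complex(ToyComplexSpec(seed=3))


@pytest.fixture(scope="session")
def clash_case():
    """The frozen challenging cross-docking fixture."""
    return make_clash_fixture()


@pytest.fixture(scope="session")
def mild_case(holo_complex):
    """A mildly perturbed (typical-difficulty) cross-docking case."""
    return make_cross_dock_case(holo_complex, CrossDockSpec(0.2, 2, seed=3))


@pytest.fixture
def holo_box(holo_complex):
    _, ligand, reference = holo_complex
    return SearchBox.around(reference.coords[ligand.heavy_indices], margin=2.0)


@pytest.fixture
def fast_sampler():
    """Small search budget for structural/contract tests."""
    return SamplerConfig(seed=1, n_chains=3, n_steps=240)


@pytest.fixture
def rescue_sampler():
    """Search budget large enough to resolve clash-rescue behavior."""
    return SamplerConfig(seed=1, n_chains=6, n_steps=1200)


@pytest.fixture
def normal_params():
    return ScoringParams()


@pytest.fixture
def soft_params():
    return ScoringParams(mode="soft")


@pytest.fixture
def rng():
    return np.random.default_rng(20231130)
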
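"""Shared fixtures: canonical genes, unit models and a fixture bundle dir."""

from __future__ import annotations

import numpy as np
import pytest

from rdnakit import archetypes
from rdnakit.unit_model import RdnaUnitModel, Subregion


@pytest.fixture(scope="session")
def canonical():
    return archetypes.make_canonical_genes(np.random.default_rng(7))


@pytest.fixture(scope="session")
def gm5s_unit(canonical):
    """627-bp 5S unit with an NTS-embedded diverged pseudogene."""
    return archetypes.make_5s_unit_with_pseudogene(
        "gm5S", canonical, np.random.default_rng(8)
    )


@pytest.fixture(scope="session")
def l_unit(canonical):
    """Linked 35S-5S unit with ITS1 subrepeats and two truncated pseudogenes."""
    return archetypes.make_l_unit("eaL", canonical, np.random.default_rng(9))


@pytest.fixture(scope="session")
def unit_700(canonical):
    """Plain 700-bp 5S unit (120-bp gene + 580-bp NTS)."""
    return archetypes.make_simple_5s_unit(
        "sim5S", canonical, np.random.default_rng(10), nts_length=580
    )


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The three archetype bundles, generated once per session."""
    from rdnakit.cli_report import generate_fixtures

    out = tmp_path_factory.mktemp("bundles")
    generate_fixtures(out, seed=1)
    return out


def make_unit(name="u", n=600, seed=0, subs=None, arrangement="S_5S"):
    """Small helper for ad-hoc unit models over random sequence."""
    from rdnakit.simulate import random_dna

    seq = random_dna(n, 0.5, np.random.default_rng(seed))
    if subs is None:
        subs = (Subregion("5S", 0, min(120, n)),)
    return RdnaUnitModel(name=name, sequence=seq, subregions=tuple(subs), arrangement=arrangement)
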
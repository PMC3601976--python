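"""Shared fixtures: the default synthetic dataset and its screen results.

Heavy objects are session-scoped so the translated search over the default
fixture runs once for the whole suite.
"""

from __future__ import annotations

import pytest

from xenoscan.synthetic_data import SimScenario, make_transcriptome_fixture


@pytest.fixture(scope="session")
def default_scenario() -> SimScenario:
    return SimScenario(seed=1)


@pytest.fixture(scope="session")
def default_fixture(default_scenario):
    """(contigs, references, taxon_map, truth) for the default scenario."""
    return make_transcriptome_fixture(default_scenario)


@pytest.fixture(scope="session")
def screen_results(default_fixture):
    from xenoscan.hgt_screen import run_screen

    contigs, refs, taxon_map, _ = default_fixture
    return run_screen(contigs, refs, taxon_map)
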
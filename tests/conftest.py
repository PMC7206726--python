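"""Shared fixtures: synthetic study scenarios and a seven-taxon tree."""

from __future__ import annotations

import numpy as np
import pytest

from holoplast import igt_locator as il
from holoplast import synthetic_data as sd
from holoplast.genome_io import PhyloTree

SEVEN_TAXON_NEWICK = (
    "(((Aindica:0.08,((Saspera:0.03,(Sforbesii:0.02,Shermonthica:0.02):0.015)"
    ":0.02,Bamericana:0.05):0.03):0.05,Lphilippensis:0.07):0.03,Rglutinosa:0.09);"
)

SEVEN_TAXON_CLASSES = {
    "Aindica": "holoparasitic",
    "Saspera": "hemiparasitic",
    "Sforbesii": "hemiparasitic",
    "Shermonthica": "hemiparasitic",
    "Bamericana": "hemiparasitic",
    "Lphilippensis": "autotrophic",
    "Rglutinosa": "autotrophic",
}


def make_seven_taxon_tree() -> PhyloTree:
    tree = PhyloTree.from_newick_string(SEVEN_TAXON_NEWICK)
    tree.assign_branch_classes(SEVEN_TAXON_CLASSES)
    return tree


@pytest.fixture()
def seven_taxon_tree() -> PhyloTree:
    return make_seven_taxon_tree()


@pytest.fixture(scope="session")
def degraded_sim():
    """Degraded plastome under the default study-shaped edits (seed 1)."""
    config = sd.SimConfig(seed=1, edits=sd.default_degradation_edits())
    degraded, truth = sd.simulate_degraded_plastome(config)
    return config, degraded, truth


@pytest.fixture(scope="session")
def igt_scenario():
    """Default transfer scenario: 20 planted fragments, 500/50/5 depths."""
    config = sd.SimConfig(seed=3, edits=sd.default_degradation_edits(),
                          transfer=sd.TransferSpec(n_fragments=20),
                          mito_len=60_000, nuclear_len=150_000)
    return config, sd.simulate_igt_scenario(config)


@pytest.fixture(scope="session")
def igt_run(igt_scenario):
    """Full pipeline result on the default transfer scenario."""
    _, scenario = igt_scenario
    proteins = il.reference_proteome(scenario.reference)
    result = il.run_igt_pipeline(scenario.reads, [scenario.reference],
                                 scenario.degraded, proteins,
                                 scenario.transcripts)
    return scenario, result


def random_signed_order(rng: np.random.Generator, n: int):
    names = [f"g{i:02d}" for i in range(n)]
    return [(name, int(rng.choice([1, -1]))) for name in names]
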
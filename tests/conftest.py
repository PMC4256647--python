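"""Shared fixtures: heavy synthetic datasets are built once per session."""

import pytest

from ptmcross import predictor as pred
from ptmcross import simulate as sim
from ptmcross.io import read_newick_string, windows_for_sites


@pytest.fixture(scope="session")
def standard_dataset():
    """The standard motif benchmark: 200 positives / 1,000 negatives, seed 42."""
    dataset, truth = sim.generate_motif_dataset(sim.standard_motif_spec(42))
    return dataset


@pytest.fixture(scope="session")
def base_model(standard_dataset):
    """Untrained model: BLOSUM62, unit weights, (7, 7) window."""
    positives = windows_for_sites(
        standard_dataset.proteins, standard_dataset.positives("sulfation"), 7, 7
    )
    return pred.GPSModel.default(positives)


@pytest.fixture(scope="session")
def base_loo(base_model, standard_dataset):
    return pred.loo_validation(base_model, standard_dataset)


@pytest.fixture(scope="session")
def trained_model(standard_dataset):
    """Full training pipeline on the standard fixture (seed 42)."""
    return pred.train(standard_dataset, wt_iterations=100, mm_iterations=100, seed=42)


@pytest.fixture(scope="session")
def ortholog_bundle():
    """Ortholog groups with planted 0.8 / 0.5 conservation, seed 7."""
    spec = sim.SyntheticSpec(seed=7)
    groups, sites, hits, truth = sim.generate_ortholog_set(spec)
    tree = read_newick_string(sim.SPECIES_TREE_NEWICK)
    return {"groups": groups, "sites": sites, "hits": hits, "truth": truth, "tree": tree}
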
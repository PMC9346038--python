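"""Shared fixtures: small simulated datasets with known selection truth.

Everything is generated at test time from fixed seeds; no data files are
stored. The `tiny` family keeps global fits cheap for logic tests, while
`bench` uses a taxon-rich tree (what gives per-site FEL its power) for
sensitivity checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import codonsel as cs


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 taxa x 40 codons: a purified block and a neutral block."""
    config = cs.SimulationConfig(n_taxa=8, tree_shape="yule", tree_length=2.5, seed=421)
    profile = cs.make_site_profile([(1, 20, 0.1, "low"), (21, 40, 1.0, "free")], 40)
    alignment, tree, truth = cs.simulate_codon_alignment(config, profile)
    return alignment, tree, truth, profile


@pytest.fixture(scope="session")
def tiny_fit(tiny_dataset):
    alignment, tree, _, _ = tiny_dataset
    return cs.fit_global_model(alignment, tree)


@pytest.fixture(scope="session")
def bench_dataset():
    """48 taxa x 36 codons: invariant start Met, strong purifying block,
    neutral block, and one planted positive site; true tree kept."""
    blocks = [
        (1, 1, 0.0, "M1"),
        (2, 18, 0.05, "core"),
        (19, 30, 1.0, "free"),
        (31, 36, 0.6, "tail"),
    ]
    profile = cs.make_site_profile(blocks, 36, invariant_start_met=True)
    profile.beta[32] = 2.5  # site 33: planted positive selection
    config = cs.SimulationConfig(n_taxa=48, tree_shape="yule", tree_length=6.0, seed=77)
    alignment, tree, truth = cs.simulate_codon_alignment(config, profile)
    return alignment, tree, truth, profile


@pytest.fixture(scope="session")
def bench_fit(bench_dataset):
    alignment, tree, _, _ = bench_dataset
    # branch lengths are already in model units from the simulator
    return cs.fit_global_model(alignment, tree, optimize_branches=False)


@pytest.fixture(scope="session")
def bench_scan(bench_fit):
    return cs.fel_scan(bench_fit, p_threshold=0.1, compute_ci=True)


@pytest.fixture()
def rng():
    """Fresh, fixed-seed generator per test: draws never depend on test order."""
    return np.random.default_rng(20240)
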
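"""Shared fixtures: small hand-checkable systems and the full study grid."""

from __future__ import annotations

import numpy as np
import pytest

import grnbench as gb

#: master seed of the study-profile grid used by the acceptance-level tests
GRID_SEED = 1234


@pytest.fixture()
def small_system():
    """20-gene stable network + knockdown design + noise-free steady state."""
    net = gb.generate_scale_free_network(20, 3.0, seed=42)
    design = gb.make_single_knockdown_design(20, 3)
    x = gb.simulate_steady_state(net, design)
    return net, design, x


@pytest.fixture()
def medium_system():
    """100-gene study-scale system (noise-free)."""
    net = gb.generate_scale_free_network(100, 3.0, seed=7)
    design = gb.make_single_knockdown_design(100, 3)
    x = gb.simulate_steady_state(net, design)
    return net, design, x


@pytest.fixture(scope="session")
def study_grid():
    """The benchmark's standard profile: 5 networks x 100 genes x 3 SNR levels.

    All seven estimators run on every dataset (tree ensemble at the reduced
    100-tree test profile) and every design-based estimator is additionally
    run against a deranged design.  Built once per session; several
    acceptance-level tests read different slices of it.
    """
    config = gb.BenchmarkConfig(
        n_networks=5,
        n_genes=100,
        replicates=3,
        snr_levels=(0.01, 0.1, 1.0),
        n_trees=100,
        scramble_control=True,
        master_seed=GRID_SEED,
    )
    report = gb.run_benchmark(config)
    assert not report.any_failed, report.to_frame().to_string()
    return report


@pytest.fixture(scope="session")
def p_based_methods():
    return [m for m, c in gb.METHOD_CATEGORIES.items() if c == "p_based"]


@pytest.fixture(scope="session")
def non_p_methods():
    return [m for m, c in gb.METHOD_CATEGORIES.items() if c == "non_p_based"]


def dense_grn(weights, category="p_based", directed=True, name="test"):
    """Convenience wrapper for hand-built score matrices."""
    return gb.ScoredGRN(
        method_name=name,
        category=category,
        directed=directed,
        dense_weights=np.asarray(weights, dtype=float),
    )
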
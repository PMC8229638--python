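"""Shared fixtures: expensive simulation results computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import cornesim as cs


@pytest.fixture(scope="session")
def protocol_results():
    """Full humidity protocol at the default resolution."""
    return cs.run_protocol()


@pytest.fixture(scope="session")
def thickness_results():
    """Swelling vs constant-thickness study for the three electrodes at 1 MHz."""
    return {
        name: cs.thickness_influence_experiment(el)
        for name, el in cs.default_electrodes().items()
    }


@pytest.fixture(scope="session")
def family_ratio_results():
    return cs.conductance_vs_capacitance_ratio()


@pytest.fixture(scope="session")
def gap_sweep_results():
    gaps = [0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20, 0.24, 0.32]
    return cs.dimension_sweep("interdigitated_conductance", "gap", gaps)
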
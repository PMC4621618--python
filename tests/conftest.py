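"""Shared fixtures.

Expensive simulation runs are session-scoped so that several tests can
interrogate the same trajectory/event log instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from germsim.germline import build_germline_qn
from germsim.hybrid import System, preset


@pytest.fixture(scope="session")
def germline_spec():
    return build_germline_qn()


@pytest.fixture(scope="session")
def germline_timed_spec():
    return build_germline_qn("timed_ras")


@pytest.fixture(scope="session")
def tiny_run():
    """A 6-hour tiny-gonad wild-type run (steady seeding, fast growth)."""
    system = System(preset("tiny", seed=7, duration=6 * 3600.0))
    system.run()
    return system


@pytest.fixture(scope="session")
def mini_run():
    """The desk-scale wild-type scenario: mini gonad, ~150 cells, 2 simulated
    days of steady flow.  This is the run the apoptosis-fraction and
    homeostasis checks interrogate."""
    system = System(preset("mini_wildtype", seed=11))
    system.run()
    return system


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
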
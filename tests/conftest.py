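"""Shared fixtures: the default parameter set and cached steady-state runs.

Simulations are memoized in a session-wide cache so that expensive
steady-state trains (20 beats each) are computed once and reused across
test modules.
"""

import numpy as np
import pytest

from cardioloop.params import ModelParams
from cardioloop.protocols import (ProtocolSpec, SimCache, run_isometric,
                                  run_workloop)


@pytest.fixture(scope="session")
def params():
    return ModelParams.default()


@pytest.fixture(scope="session")
def cache():
    return SimCache()


@pytest.fixture(scope="session")
def iso_lo(params, cache):
    """Steady-state L_o isometric twitch (also computes the normalization)."""
    return run_isometric(params.l_o, params, cache=cache)


@pytest.fixture(scope="session")
def iso_short(params, cache):
    return run_isometric(1.95, params, cache=cache)


@pytest.fixture(scope="session")
def iso_mid(params, cache):
    return run_isometric(2.1, params, cache=cache)


def _workloop(params, cache, afterload, **kw):
    spec = ProtocolSpec(mode="workloop", afterload=afterload, **kw)
    return run_workloop(spec, params, cache=cache)


@pytest.fixture(scope="session")
def wl_low(params, cache, iso_lo):
    return _workloop(params, cache, 0.2)


@pytest.fixture(scope="session")
def wl_mid(params, cache, iso_lo):
    return _workloop(params, cache, 0.45)


@pytest.fixture(scope="session")
def wl_high(params, cache, iso_lo):
    return _workloop(params, cache, 0.8)


@pytest.fixture(scope="session")
def wl_unit(params, cache, iso_lo):
    return _workloop(params, cache, 1.0)
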
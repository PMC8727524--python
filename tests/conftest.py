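"""Shared fixtures: constructed sweeps and cached simulations."""

from __future__ import annotations

import numpy as np
import pytest

import drgsim as d
from drgsim.neuron_model import ChannelSpec, NeuronParams, SimConfig, default_params
from drgsim.sweeps import Sweep


def make_sweep(t, v, i=None, **meta) -> Sweep:
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if i is None:
        i = np.zeros_like(t)
    return Sweep(t=t, v=v, i=np.asarray(i, dtype=float), meta=meta)


def passive_cell(g_leak: float = 10.0, e_leak: float = -65.0, cm: float = 25.0) -> NeuronParams:
    """A cell with only a leak conductance (analytic RC behaviour)."""
    return NeuronParams(
        cm=cm,
        channels=(ChannelSpec("leak", g_leak, e_leak),
                  ChannelSpec("hcn", 0.0, -60.0)),
        label="WT",
    )


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def wt_params():
    return default_params("WT")


@pytest.fixture(scope="session")
def ko_params():
    return default_params("KO")


@pytest.fixture(scope="session")
def wt_step_sweeps(wt_params, sim_config):
    """Default WT cell run through the full step family."""
    return d.simulate(wt_params, d.step_family(), sim_config)


@pytest.fixture(scope="session")
def wt_ramp_sweep(wt_params, sim_config):
    return d.simulate(wt_params, d.ramp(), sim_config)[0]


@pytest.fixture(scope="session")
def wt_sag_sweeps(wt_params, sim_config):
    return d.simulate(wt_params, d.sag_family(), sim_config)


@pytest.fixture(scope="session")
def wt_rin_sweep(wt_params, sim_config):
    return d.simulate(wt_params, d.rin_pulse(), sim_config)[0]
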
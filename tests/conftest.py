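"""Shared fixtures: calibrated parameters and cached heavy simulations."""

import numpy as np
import pytest

from erkpulse import (CellEnsembleSpec, StimulusProtocol, build_parameters,
                      simulate_deterministic, simulate_ensemble)
from erkpulse.stimulus import make_pulse_train, make_sustained

STIM_START = 10.0


@pytest.fixture(scope="session")
def full_params():
    return build_parameters("FULL")


@pytest.fixture(scope="session")
def sustained_high_egf(full_params):
    return simulate_deterministic(full_params, make_sustained("EGF", 25, STIM_START, 75))


@pytest.fixture(scope="session")
def sustained_high_ngf(full_params):
    return simulate_deterministic(full_params, make_sustained("NGF", 50, STIM_START, 75))


def single_pulse(gf, dose, minutes, tail=60.0):
    return StimulusProtocol(gf, dose, STIM_START, ((float(minutes), True), (tail, False)))


@pytest.fixture(scope="session")
def ensemble_pulses(full_params):
    """Sustained-classification ensembles for the four NGF pulse conditions.

    1000 cells per condition with lognormal (sigma 0.25) total abundances.
    """
    out = {}
    for key, dose, dur in (("h10", 50.0, 10.0), ("l10", 2.0, 10.0),
                           ("h3", 50.0, 3.0), ("l3", 2.0, 3.0)):
        spec = CellEnsembleSpec(n_cells=1000, seed=20150)
        out[key] = simulate_ensemble(spec, full_params, single_pulse("NGF", dose, dur))
    return out


@pytest.fixture(scope="session")
def train_decay_ratios(full_params):
    """Decay ratio of per-pulse maxima for 3'-pulse trains over ~5 h."""
    from erkpulse.metrics import pulse_maxima_decay
    from erkpulse.scan import train_protocol

    out = {}
    for pause in (10.0, 20.0, 60.0):
        for gf, dose, tag in (("EGF", 25.0, "egf_high"), ("EGF", 1.0, "egf_low"),
                              ("NGF", 50.0, "ngf_high")):
            pr = train_protocol(gf, dose, 3.0, pause, STIM_START, 300.0)
            tr = simulate_deterministic(full_params, pr)
            _, ratio = pulse_maxima_decay(tr, pr)
            out[(pause, tag)] = ratio
    return out
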
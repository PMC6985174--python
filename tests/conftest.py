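"""Shared fixtures: default circuits, phenotypes, and simulated traces.

Expensive simulations are session-scoped so the detection and acceptance
tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from impedancyte import (
    CellPhenotype,
    FrequencyPanel,
    SystemCircuit,
    pulse_amplitude,
)
from impedancyte.synth import (
    AcquisitionSpec,
    LogNormalSpec,
    PopulationSpec,
    sample_population,
    synthesize_trace,
)


@pytest.fixture(scope="session")
def system():
    return SystemCircuit()


@pytest.fixture(scope="session")
def panel():
    return FrequencyPanel()


@pytest.fixture(scope="session")
def live_phenotype():
    return CellPhenotype(diameter_um=4.6, group="live")


@pytest.fixture(scope="session")
def dead_phenotype():
    """Heat-killed construction: leaky membrane (100x g_mem), 0.8x diameter."""
    return CellPhenotype(diameter_um=4.6 * 0.8, g_mem=500.0, group="dead")


@pytest.fixture(scope="session")
def bead_phenotype():
    return CellPhenotype(
        diameter_um=3.0,
        g_mem=1e-6,
        c_mem_spec=1e-6,
        sigma_cyto=1e-6,
        eps_cyto=2.6,
        group="bead",
    )


def snr10_noise(phenotypes, system, panel):
    """Noise sd giving SNR 10 on the reference channel for this population."""
    mean_amp = float(
        np.mean([pulse_amplitude(system, p, panel)[0] for p in phenotypes])
    )
    return mean_amp / 10.0


@pytest.fixture(scope="session")
def snr10_trace(system, panel):
    """200-event live-population trace at SNR 10, with its ground truth."""
    spec = PopulationSpec(n_cells=200, group="live")
    phenotypes = sample_population(spec, 11)
    acq = AcquisitionSpec(noise_sigma=snr10_noise(phenotypes, system, panel))
    trace, truth = synthesize_trace(phenotypes, acq, system, panel, seed=5)
    return trace, truth, acq


@pytest.fixture(scope="session")
def noiseless_trace(system, panel):
    """10-event noiseless, drift-free trace."""
    spec = PopulationSpec(n_cells=10, group="live")
    phenotypes = sample_population(spec, 3)
    acq = AcquisitionSpec(noise_sigma=0.0, drift_amplitude=0.0)
    trace, truth = synthesize_trace(phenotypes, acq, system, panel, seed=4)
    return trace, truth, acq
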
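"""Shared fixtures: one synthetic dataset generated once per session."""

import pytest

from captes.synth import (
    SimulationConfig,
    simulate_reads,
    simulate_reference,
    simulate_transcripts,
)
from captes.txclass import classify_transcripts


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def reference(sim_config):
    return simulate_reference(sim_config)


@pytest.fixture(scope="session")
def transcriptome(sim_config, reference):
    return simulate_transcripts(reference, sim_config)


@pytest.fixture(scope="session")
def sim_reads(sim_config, reference, transcriptome):
    return simulate_reads(reference, transcriptome, sim_config)


@pytest.fixture(scope="session")
def classified(reference, transcriptome):
    return classify_transcripts(
        transcriptome.transcripts, reference.genes, reference.te_loci
    )
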
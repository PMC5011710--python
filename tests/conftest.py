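import numpy as np
import pytest

from prfmap import (
    SimulationConfig,
    Transcript,
    build_euplotes_code,
    build_standard_code,
)


@pytest.fixture(scope="session")
def euplotes():
    return build_euplotes_code()


@pytest.fixture(scope="session")
def standard():
    return build_standard_code()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study with default noise, shared across tests."""
    from prfmap import run_synthetic_study

    return run_synthetic_study(SimulationConfig(n_genes=200, seed=7))


@pytest.fixture()
def toy_two_site_transcript(euplotes):
    """A hand-built transcript with two classical +1 junctions.

    Frame 0: AUG (GCU)x8 AAA | UAA at nt 30 (skip its U) ->
    frame 1: AAG (GAU)x8 AAA | UAA at nt 61 (skip its U) ->
    frame 2: AAU (GUU)x8 | terminal UAA at nt 89.
    The first codon after each skip shares the stop codon's last two
    bases, so only one extra base is appended to complete it.
    """
    seg0 = "AUG" + "GCU" * 8 + "AAA"  # 10 codons, frame 0; ends in pre-codon
    j0 = "UAA"                         # skip_pos = 30
    seg1 = "G" + "GAU" * 8 + "AAA"    # completes AAG, then D x8, pre-codon AAA
    j1 = "UAA"                         # skip_pos = 61
    seg2 = "U" + "GUU" * 8            # completes AAU, then V x8
    tail = "UAA"
    return Transcript("toy2", seg0 + j0 + seg1 + j1 + seg2 + tail)
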
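"""Shared test constants and fixtures.

The published operator sequences serve as ground truth across modules.
"""

import numpy as np
import pytest

from sprmap.seqdesign import OligoDuplex

# Starting 36-mers for the two footprinting campaigns and the determined
# 24-mer footprints.
O3204_START = "ACTCCAATACTTGAACTCTCAATCTTTACGTGCCGT"
O3205_START = "ACGCCGATTTTGTTTAATGTTCAAGGAACCGTCTCG"
O3204_FOOTPRINT = "CAATACTTGAACTCTCAATCTTTA"
O3205_FOOTPRINT = "ATTTTGTTTAATGTTCAAGGAACC"
CONSENSUS = "TTnAAnnnTCAA"

REGION_LENGTH = 119
FRAGMENT_LENGTH = 29
SITE_LENGTH = 22

CONC_SERIES_NM = (0.39, 0.78, 1.56, 3.13, 6.25, 12.5, 25.0, 50.0)


@pytest.fixture
def o3204_start():
    return OligoDuplex(name="O3204_start", forward=O3204_START)


@pytest.fixture
def o3205_start():
    return OligoDuplex(name="O3205_start", forward=O3205_START)


@pytest.fixture
def random_region():
    """Deterministic 119-nt region."""
    rng = np.random.default_rng(20130607)
    return "".join(rng.choice(list("ACGT"), size=REGION_LENGTH))


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))
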
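import numpy as np
import pytest

from flaxpop.io import HaplotypeAlignment

# A small hand-built alignment used across the neutrality tests; its
# statistics were frozen from an independent brute-force evaluation of the
# published formulas (and cross-checked against dendropy for Tajima's D).
FIXTURE_SEQS = {
    "s1": "AAAAAAAA",
    "s2": "AAAATAAA",
    "s3": "AATATAAA",
    "s4": "AATATTAA",
    "s5": "AATATTAG",
    "s6": "CATATTAG",
}

FIXTURE_EXPECTED = {
    "n": 6,
    "S": 5,
    "pi": 7.0 / 3.0,
    "singletons": 2,
    "tajima_d": 0.36689250611869356,
    "fu_li_d_star": 0.3620597963666507,
    "fu_li_f_star": 0.38669910052887113,
    "r2": 0.19148542155126763,
}


@pytest.fixture
def toy_alignment():
    return HaplotypeAlignment(FIXTURE_SEQS.items())


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
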
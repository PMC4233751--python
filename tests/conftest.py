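from fractions import Fraction

import pytest

from clonedist import CloneSizeCounts, FateProbabilities

# the in-culture keratinocyte fate estimate, used throughout as a realistic
# slightly proliferation-skewed parameter set
KERATINOCYTE_FATE = FateProbabilities(0.415, 0.278, 0.307)
KERATINOCYTE_FATE_EXACT = FateProbabilities(
    Fraction(415, 1000), Fraction(278, 1000), Fraction(307, 1000)
)

# observed counts of fully differentiated 2-, 3- and 4-cell keratinocyte
# clones from a 2086-clone culture experiment
KERATINOCYTE_COUNTS = CloneSizeCounts({2: 259, 3: 72, 4: 53}, total_clones=2086)

# fate parameter sets exercising interior and boundary behaviour
FATE_SETS_EXACT = [
    FateProbabilities(Fraction(3, 10), Fraction(4, 10), Fraction(3, 10)),  # a = c
    FateProbabilities(Fraction(1, 2), Fraction(1, 4), Fraction(1, 4)),  # a > c
    FateProbabilities(Fraction(1, 5), Fraction(3, 10), Fraction(1, 2)),  # c > a
    FateProbabilities(Fraction(0), Fraction(2, 5), Fraction(3, 5)),  # a = 0
    FateProbabilities(Fraction(3, 5), Fraction(2, 5), Fraction(0)),  # c = 0
]


@pytest.fixture
def keratinocyte_fate() -> FateProbabilities:
    return KERATINOCYTE_FATE


@pytest.fixture
def keratinocyte_counts() -> CloneSizeCounts:
    return KERATINOCYTE_COUNTS
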
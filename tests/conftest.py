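import numpy as np
import pandas as pd
import pytest

from transevol.expression import CountMatrix
from transevol.mobilome import ClassStat


@pytest.fixture
def small_counts() -> CountMatrix:
    """Six samples in two tissue groups, five transcripts, hand-set counts."""
    counts = pd.DataFrame(
        {
            "b1": [100, 200, 50, 0, 650],
            "b2": [110, 190, 55, 0, 645],
            "b3": [90, 210, 45, 0, 655],
            "l1": [400, 20, 50, 0, 530],
            "l2": [380, 25, 55, 0, 540],
            "l3": [420, 15, 45, 0, 520],
        },
        index=[f"t{i}" for i in range(1, 6)],
    )
    lengths = pd.Series([1000, 2000, 500, 800, 1500], index=counts.index)
    groups = {"b1": "brain", "b2": "brain", "b3": "brain",
              "l1": "liver", "l2": "liver", "l3": "liver"}
    return CountMatrix(counts=counts, lengths=lengths, groups=groups)


@pytest.fixture(scope="session")
def published_repeat_classes() -> dict[str, ClassStat]:
    """Per-class and subfamily repeat statistics of the lungfish
    transcriptome scan (printed leaf values; totals are derived by the
    summary writer)."""
    return {
        "SINE": ClassStat(791, 103_659),
        "LINE": ClassStat(2_668, 1_178_516, {
            "L2/CR1/Rex": ClassStat(2_118, 883_120),
            "R2/R4/NeSL": ClassStat(196, 113_911),
            "RTE/Bov-B": ClassStat(10, 1_598),
            "L1/CIN4": ClassStat(344, 179_887),
        }),
        "LTR": ClassStat(459, 126_196, {
            "Gypsy/DIRS1": ClassStat(29, 9_956),
            "Retroviral": ClassStat(429, 116_103),
        }),
        "DNA": ClassStat(1_902, 377_257, {
            "hobo-Activator": ClassStat(198, 50_625),
            "Tc1-IS630-Pogo": ClassStat(1_554, 293_330),
        }),
        "Unclassified": ClassStat(8, 2_109),
        "SmallRNA": ClassStat(46, 15_534),
        "Satellite": ClassStat(5, 412),
        "SimpleRepeat": ClassStat(25_339, 938_512),
        "LowComplexity": ClassStat(3_166, 146_658),
    }


SCANNED_BP = 116_965_448
MASKED_BP = 2_886_461


@pytest.fixture(scope="session")
def scanned_masked_bp():
    return SCANNED_BP, MASKED_BP
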
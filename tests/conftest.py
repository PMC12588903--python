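from itertools import combinations

import numpy as np
import pytest

from pmtox import SyntheticConfig, generate_compound_table


def pair_counting_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index computed by exhaustive pair counting."""
    labels_a = list(labels_a)
    labels_b = list(labels_b)
    n_pairs = same_a = same_b = both = 0
    for i, j in combinations(range(len(labels_a)), 2):
        n_pairs += 1
        sa = labels_a[i] == labels_a[j]
        sb = labels_b[i] == labels_b[j]
        same_a += sa
        same_b += sb
        both += sa and sb
    expected = same_a * same_b / n_pairs
    maximum = 0.5 * (same_a + same_b)
    if maximum == expected:
        return 1.0
    return (both - expected) / (maximum - expected)


@pytest.fixture(scope="session")
def default_table():
    """One default 61-batch synthetic compound table (seed 1)."""
    return generate_compound_table(SyntheticConfig(seed=1))
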
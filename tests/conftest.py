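from dataclasses import dataclass

import numpy as np
import pytest


@dataclass
class Rec:
    """Minimal patient-like record for rule/metric/search tests."""

    stenosis: float
    pav: float
    ischemia: bool


def make_cohort(rows):
    """Build a toy cohort from (stenosis, pav, label) triples."""
    return [Rec(float(s), float(p), bool(y)) for s, p, y in rows]


@pytest.fixture
def toy_cohort4():
    # the 4-record worked example: hand-applied classifications are frozen
    # in the tests that use it
    return make_cohort(
        [(20, 5, False), (40, 15, True), (40, 5, False), (80, 2, True)]
    )


@pytest.fixture
def toy_cohort8():
    # 8 patients spanning all three zones of a (20..80, {5,10,15}) grid
    return make_cohort(
        [
            (10, 2, False),
            (25, 12, False),
            (35, 4, False),
            (45, 14, True),
            (55, 8, False),
            (65, 18, True),
            (85, 3, True),
            (95, 30, True),
        ]
    )


def random_cohort(rng, n, p_label=0.4):
    stenosis = rng.uniform(0.0, 100.0, n)
    pav = rng.uniform(0.0, 49.0, n)
    labels = rng.random(n) < p_label
    return make_cohort(zip(stenosis, pav, labels))
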
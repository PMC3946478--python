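"""Shared fixtures: printed worked examples and tiny geometric datasets."""

import numpy as np
import pytest

from vericlust import ConfusionMatrix
from vericlust.model import TransitionSystem

# Printed 4x3 class-by-cluster contingency table of the worked example
# (rows = ground-truth classes 0..3, columns = clusters 0..2).
WORKED_TABLE_CELLS = [
    [1118, 100, 76],
    [429, 70, 64],
    [1, 3, 16],
    [27, 122, 20],
]
WORKED_TABLE_ROW_MARGINS = [1294, 563, 20, 169]
WORKED_TABLE_PRINTED_TOTAL = 2126   # the table's printed grand total


@pytest.fixture
def worked_table_cm() -> ConfusionMatrix:
    return ConfusionMatrix(np.array(WORKED_TABLE_CELLS),
                           classes=(0, 1, 2, 3), clusters=(0, 1, 2))


@pytest.fixture
def two_far_pairs() -> np.ndarray:
    """Two tight pairs 10 apart: {(0,0),(0,1)} and {(10,0),(10,1)}."""
    return np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])


def make_chain_ts(labels_per_state, initial=("S1",)) -> TransitionSystem:
    """Linear chain S1 -> ... -> ST with terminal self-loop; labels given
    as an iterable of proposition collections."""
    labels = [frozenset(l) for l in labels_per_state]
    T = len(labels)
    states = tuple(f"S{t}" for t in range(1, T + 1))
    transitions = {states[t]: frozenset({states[min(t + 1, T - 1)]})
                   for t in range(T)}
    ap = frozenset().union(*labels) if labels else frozenset()
    return TransitionSystem(
        states=states,
        transitions=transitions,
        initial=frozenset(initial),
        ap=ap | {"p", "q", "converge", "handled", "DunnUp", "maxDunn",
                 "diamDown", "minDiam"},
        labels=dict(zip(states, labels)),
    )
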
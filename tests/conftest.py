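"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's optimised code paths: the null
pmf is obtained by exhaustive enumeration of label arrangements, and the
minimisation oracle scans a dense grid of thresholds with direct counting.
"""

from itertools import combinations

import numpy as np
import pytest

from erp import LabeledSample, Weights


def enumerate_null_pmf(n0: int, n1: int, w0: float, w1: float, mode: str = "up") -> dict:
    """Exact null pmf of the minimised statistic by enumerating arrangements.

    Under H0 every placement of the ``n1`` experimental labels among the
    ``N`` ranks is equally likely; the statistic depends on the data only
    through that placement.
    """
    n = n0 + n1
    counts: dict[float, int] = {}
    total = 0
    for exp_positions in combinations(range(n), n1):
        y = np.zeros(n, dtype=int)
        y[list(exp_positions)] = 1
        best_up = w0          # cut below all points: everyone voted control
        worst_up = w0
        c1 = 0
        for k in range(1, n + 1):
            c1 += y[k - 1]
            c0 = k - c1
            er = w0 * (n0 - c0) / n0 + w1 * c1 / n1
            best_up = min(best_up, er)
            worst_up = max(worst_up, er)
        best_down = 1.0 - worst_up
        if mode == "up":
            value = best_up
        elif mode == "down":
            value = best_down
        else:
            value = min(best_up, best_down)
        value = round(value, 12)
        counts[value] = counts.get(value, 0) + 1
        total += 1
    return {v: c / total for v, c in sorted(counts.items())}


def grid_minimum_error(values, labels, w0: float, w1: float, mode: str = "up",
                       n_grid: int = 10_000) -> float:
    """Minimum error rate over a dense grid of thresholds, by direct counting."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    span = x.max() - x.min() if x.max() > x.min() else 1.0
    grid = np.linspace(x.min() - span, x.max() + span, n_grid)
    ctrl_above = ((x[y == 0][:, None]) > grid[None, :]).sum(axis=0)
    exp_below = ((x[y == 1][:, None]) <= grid[None, :]).sum(axis=0)
    er_up = w0 * ctrl_above / n0 + w1 * exp_below / n1
    if mode == "up":
        return float(er_up.min())
    if mode == "down":
        return float((1.0 - er_up).min())
    return float(min(er_up.min(), (1.0 - er_up).min()))


@pytest.fixture(scope="session")
def weight_sets():
    return {1: Weights(0.5, 0.5), 2: Weights(1.0 / 3.0, 2.0 / 3.0)}


@pytest.fixture
def separable_sample():
    """Toy upward-shifted sample that a single threshold separates."""
    return LabeledSample([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(20160114)
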
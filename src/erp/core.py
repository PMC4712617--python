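"""Weighted misclassification error rates and their minimisation over thresholds.

A single variable ``X`` is measured on ``N0`` control and ``N1`` experimental
subjects.  The *upward rule* with threshold ``c`` classifies a subject as
experimental when ``X > c`` and as control when ``X <= c``; the *downward
rule* reverses the comparison.  The weighted combined error rate of the
upward rule is

    er_up(c) = w0 * (1 - F0(c)) + w1 * F1(c)

where ``F0``/``F1`` are the group CDFs and the costs ``w0 + w1 = 1``.  Its
empirical estimate replaces the CDFs by empirical counts.  Because the
estimate is a step function of ``c`` that only changes at data values, it is
minimised exactly by scanning the midpoints between consecutive distinct
sorted values, plus two sentinel thresholds (below the minimum and above the
maximum) that represent the degenerate classify-everyone-one-way rules.

The minimised statistic depends on the data only through the group labels of
the ranked observations, which is what makes it distribution-free under the
null hypothesis of no shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Weights",
    "LabeledSample",
    "MinimizationResult",
    "error_rate_up",
    "error_rate_down",
    "minimize_rule",
    "WEIGHT_PRESETS",
]

Mode = Literal["up", "down", "min"]

#: Cost configurations used throughout: preset 1 weighs both misclassification
#: types equally; preset 2 doubles the cost of missing an experimental subject.
WEIGHT_PRESETS = {1: (0.5, 0.5), 2: (1.0 / 3.0, 2.0 / 3.0)}


@dataclass(frozen=True)
class Weights:
    """Misclassification-cost pair ``(w0, w1)`` with ``w0 + w1 = 1``.

    ``w0`` is the cost of misclassifying a control subject, ``w1`` the cost
    of misclassifying an experimental subject.
    """

    w0: float = 0.5
    w1: float = 0.5

    def __post_init__(self) -> None:
        if not (self.w0 > 0 and self.w1 > 0):
            raise ValueError(f"weights must be positive, got ({self.w0}, {self.w1})")
        if abs(self.w0 + self.w1 - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {self.w0 + self.w1!r}")

    @classmethod
    def from_preset(cls, preset: int) -> "Weights":
        """Return weight set 1, ``(1/2, 1/2)``, or weight set 2, ``(1/3, 2/3)``."""
        try:
            w0, w1 = WEIGHT_PRESETS[preset]
        except KeyError:
            raise ValueError(f"unknown weight preset {preset!r}; use 1 or 2") from None
        return cls(w0, w1)

    @property
    def minimum(self) -> float:
        return min(self.w0, self.w1)


@dataclass(frozen=True)
class LabeledSample:
    """Feature values paired with binary group labels for one variable."""

    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.ndim != 1 or labels.ndim != 1 or values.shape != labels.shape:
            raise ValueError(
                f"values and labels must be 1-d and of equal length, got shapes "
                f"{values.shape} and {labels.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("all values must be finite")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (experimental)")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError(
                f"both groups must be non-empty, got n0={self.n0}, n1={self.n1}"
            )

    @property
    def n0(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 1))

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MinimizationResult:
    """Minimised error rate, its threshold and shift direction for one variable."""

    error_rate: float
    threshold: float
    direction: Literal["up", "down"]
    mode: Mode


def error_rate_up(sample: LabeledSample, weights: Weights, c: float) -> float:
    """Empirical upward-rule error rate at threshold ``c``.

    ``(w0/N0) * #{controls with x > c} + (w1/N1) * #{experimentals with x <= c}``.
    """
    x, y = sample.values, sample.labels
    n_ctrl_above = np.sum((y == 0) & (x > c))
    n_exp_below = np.sum((y == 1) & (x <= c))
    return weights.w0 * n_ctrl_above / sample.n0 + weights.w1 * n_exp_below / sample.n1


def error_rate_down(sample: LabeledSample, weights: Weights, c: float) -> float:
    """Empirical downward-rule error rate at ``c``; equals ``1 - error_rate_up(c)``."""
    x, y = sample.values, sample.labels
    n_ctrl_below = np.sum((y == 0) & (x <= c))
    n_exp_above = np.sum((y == 1) & (x > c))
    return weights.w0 * n_ctrl_below / sample.n0 + weights.w1 * n_exp_above / sample.n1


def _candidate_cuts(x_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate thresholds for the step-function minimisation.

    Returns ``(cut_counts, thresholds)`` where ``cut_counts[i]`` is the number
    of (sorted) observations at or below ``thresholds[i]``.  Candidates are
    the midpoints between consecutive *distinct* sorted values plus two
    sentinels at ``min - g`` and ``max + g`` with ``g`` the median gap between
    consecutive distinct values (1.0 when all values coincide).
    """
    n = x_sorted.shape[0]
    distinct_after = np.nonzero(np.diff(x_sorted) > 0)[0] + 1  # cut positions 1..n-1
    gaps = np.diff(np.unique(x_sorted))
    g = float(np.median(gaps)) if gaps.size else 1.0
    cuts = np.concatenate(([0], distinct_after, [n]))
    thresholds = np.empty(cuts.shape[0])
    thresholds[0] = x_sorted[0] - g
    thresholds[-1] = x_sorted[-1] + g
    inner = cuts[1:-1]
    thresholds[1:-1] = 0.5 * (x_sorted[inner - 1] + x_sorted[inner])
    return cuts, thresholds


def _error_curves(
    sample: LabeledSample, weights: Weights
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Up- and down-rule error rates at every candidate threshold.

    Both curves are computed directly in the form ``w0*j/N0 + w1*k/N1`` so
    that equal lattice values produce bit-identical floats for either
    direction (``1 - er_up`` would differ in the last ulp).
    """
    order = np.argsort(sample.values, kind="stable")
    x_sorted = sample.values[order]
    y_sorted = sample.labels[order]
    cuts, thresholds = _candidate_cuts(x_sorted)
    cum1 = np.concatenate(([0], np.cumsum(y_sorted)))  # experimentals at or below cut
    n_exp_below = cum1[cuts]
    n_ctrl_below = cuts - n_exp_below
    w0, w1 = weights.w0, weights.w1
    n0, n1 = sample.n0, sample.n1
    er_up = w0 * (n0 - n_ctrl_below) / n0 + w1 * n_exp_below / n1
    er_down = w0 * n_ctrl_below / n0 + w1 * (n1 - n_exp_below) / n1
    return er_up, er_down, thresholds


def minimize_rule(sample: LabeledSample, weights: Weights, mode: Mode = "min") -> MinimizationResult:
    """Minimise the weighted error rate over candidate thresholds.

    ``mode="up"`` / ``"down"`` fix the shift direction; ``mode="min"`` takes
    the smaller of the two minima, resolving an exact tie to ``"down"``.
    When several thresholds achieve the minimum the smallest one is returned.
    """
    if mode not in ("up", "down", "min"):
        raise ValueError(f"mode must be 'up', 'down' or 'min', got {mode!r}")
    er_up, er_down, thresholds = _error_curves(sample, weights)
    i_up = int(np.argmin(er_up))
    if mode == "up":
        return MinimizationResult(float(er_up[i_up]), float(thresholds[i_up]), "up", mode)
    i_down = int(np.argmin(er_down))
    if mode == "down":
        return MinimizationResult(
            float(er_down[i_down]), float(thresholds[i_down]), "down", mode
        )
    # direction-free rule: exact float comparison, ties go to "down"
    if er_up[i_up] < er_down[i_down]:
        return MinimizationResult(float(er_up[i_up]), float(thresholds[i_up]), "up", mode)
    return MinimizationResult(float(er_down[i_down]), float(thresholds[i_down]), "down", mode)


def batch_minimized_error_rates(
    x: np.ndarray, labels: np.ndarray, weights: Weights, mode: Mode = "up"
) -> np.ndarray:
    """Minimised error rates for many samples at once.

    ``x`` has shape ``(R, N)``: R independent samples sharing one label
    vector.  Values within each row are assumed continuous (no ties), which
    holds almost surely for the simulated draws this fast path serves; every
    cut between consecutive order statistics, including the two degenerate
    end cuts, is then a candidate.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    n1 = int(labels.sum())
    n0 = n - n1
    order = np.argsort(x, axis=1)
    y_sorted = labels[order]
    cum1 = np.cumsum(y_sorted, axis=1)
    k = np.arange(1, n + 1)
    w0, w1 = weights.w0, weights.w1
    er_up = np.empty((x.shape[0], n + 1))
    er_up[:, 0] = w0
    er_up[:, 1:] = w0 * (n0 - (k - cum1)) / n0 + w1 * cum1 / n1
    if mode == "up":
        return er_up.min(axis=1)
    er_down = np.empty_like(er_up)
    er_down[:, 0] = w1
    er_down[:, 1:] = w0 * (k - cum1) / n0 + w1 * (n1 - cum1) / n1
    if mode == "down":
        return er_down.min(axis=1)
    return np.minimum(er_up.min(axis=1), er_down.min(axis=1))
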
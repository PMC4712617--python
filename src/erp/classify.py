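"""Classification of unseen subjects with the selected per-variable rules.

Each selected variable contributes one vote: under its upward rule a subject
is voted experimental when its value exceeds the variable's threshold
(control when the value is at or below it); the downward rule reverses the
comparison.  The final label is the majority vote, with an even split
resolved toward the costlier misclassification (experimental when
``w1 >= w0``).  When the true labels are known, subjects misclassified by
unusually many individual variables are flagged as potential outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationReport",
    "classify_subject",
    "classify_matrix",
    "classify_from_rules",
    "flag_outliers",
]


@dataclass
class ClassificationReport:
    """Per-subject, per-variable votes plus the majority-vote labels."""

    votes: pd.DataFrame  # subjects x selected variables, entries in {0, 1}
    final_label: np.ndarray
    truth: np.ndarray | None = None
    misclassified: np.ndarray | None = None
    miscount: np.ndarray | None = None  # per-subject count of misvoting variables
    outlier: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Votes table with final/misclassified/outlier columns appended."""
        frame = self.votes.copy()
        frame["final"] = self.final_label
        if self.truth is not None:
            frame["truth"] = self.truth
            frame["misclassified"] = self.misclassified.astype(int)
            frame["outlier"] = self.outlier.astype(int)
        return frame


def _votes(values: np.ndarray, thresholds: np.ndarray, directions: np.ndarray) -> np.ndarray:
    up = directions == "up"
    votes = np.where(up, values > thresholds, values <= thresholds)
    return votes.astype(int)


def _majority(votes: np.ndarray, w0: float, w1: float) -> np.ndarray:
    n_rules = votes.shape[-1]
    n_exp = votes.sum(axis=-1)
    tie_label = 1 if w1 >= w0 else 0
    final = np.where(2 * n_exp > n_rules, 1, np.where(2 * n_exp < n_rules, 0, tie_label))
    return final.astype(int)


def classify_subject(values, rules, *, w0: float = 0.5, w1: float = 0.5):
    """Votes and majority label for one subject.

    ``rules`` is a sequence of ``(threshold, direction)`` pairs, one per
    selected variable, aligned with ``values``.
    """
    rules = list(rules)
    if not rules:
        raise ValueError("no significant variables: empty rule list")
    values = np.asarray(values, dtype=float)
    if values.shape != (len(rules),):
        raise ValueError(f"expected one value per rule, got {values.shape[0]} values for {len(rules)} rules")
    if not np.all(np.isfinite(values)):
        raise ValueError("all values must be finite")
    thresholds = np.array([c for c, _ in rules], dtype=float)
    directions = np.array([d for _, d in rules])
    votes = _votes(values, thresholds, directions)
    final = int(_majority(votes[None, :], w0, w1)[0])
    return votes, final


def classify_matrix(
    test_matrix, selection, truth=None, var_names=None, weight_votes=False
) -> ClassificationReport:
    """Classify every row of ``test_matrix`` with a fitted selection.

    ``selection`` is an :class:`~erp.model.ERpResults`; only its significant
    variables vote.  ``test_matrix`` may be a DataFrame (matched to the
    selected variables by column name) or an array whose columns follow
    ``var_names`` (defaulting to the fitted model's variable order).
    """
    rules = selection.rules
    if rules.empty:
        raise ValueError("no significant variables: nothing to classify with")
    if isinstance(test_matrix, pd.DataFrame):
        frame = test_matrix
    else:
        arr = np.asarray(test_matrix, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        names = var_names if var_names is not None else selection.model.var_names
        frame = pd.DataFrame(arr, columns=[str(n) for n in names])
    weights = selection.model.weights
    return classify_from_rules(
        frame, rules, weights.w0, weights.w1, truth=truth, weight_votes=weight_votes
    )


def classify_from_rules(
    frame: pd.DataFrame,
    rules: pd.DataFrame,
    w0: float,
    w1: float,
    truth=None,
    weight_votes: bool = False,
) -> ClassificationReport:
    """Classify a DataFrame of subjects given a rules table.

    ``rules`` needs columns ``variable``, ``threshold`` and ``direction``;
    subjects are matched to rules by column name.  With
    ``weight_votes=True`` (off by default) each variable's vote is weighted
    by ``-log10(p_value)`` instead of counting equally, giving the most
    significant variables the loudest voice; ``rules`` must then carry a
    ``p_value`` column.
    """
    if rules.empty:
        raise ValueError("no significant variables: empty rule table")
    missing = [v for v in rules["variable"] if v not in frame.columns]
    if missing:
        raise ValueError(f"selected variable(s) missing from test matrix: {missing}")
    sub = frame[list(rules["variable"])].to_numpy(dtype=float)
    if not np.all(np.isfinite(sub)):
        raise ValueError("test matrix contains non-finite values in selected variables")
    thresholds = rules["threshold"].to_numpy(dtype=float)
    directions = rules["direction"].to_numpy()
    votes = _votes(sub, thresholds, directions)
    if weight_votes:
        if "p_value" not in rules.columns:
            raise ValueError("weight_votes=True requires a p_value column in the rules")
        vote_weights = -np.log10(np.clip(rules["p_value"].to_numpy(dtype=float), 1e-300, 1.0))
        exp_mass = (votes * vote_weights).sum(axis=1)
        ctrl_mass = ((1 - votes) * vote_weights).sum(axis=1)
        tie_label = 1 if w1 >= w0 else 0
        final = np.where(
            exp_mass > ctrl_mass, 1, np.where(exp_mass < ctrl_mass, 0, tie_label)
        ).astype(int)
    else:
        final = _majority(votes, w0, w1)
    votes_frame = pd.DataFrame(votes, columns=list(rules["variable"]), index=frame.index)
    report = ClassificationReport(votes=votes_frame, final_label=final)
    if truth is not None:
        truth = np.asarray(truth, dtype=int)
        if truth.shape != (sub.shape[0],):
            raise ValueError("truth must supply one label per test subject")
        report.truth = truth
        report.misclassified = final != truth
        report.miscount = (votes != truth[:, None]).sum(axis=1)
        report.outlier = flag_outliers(report, truth)
    return report


def flag_outliers(report: ClassificationReport, truth) -> np.ndarray:
    """Flag subjects misvoted by unusually many variables.

    A subject is flagged when its per-variable misclassification count is at
    least ``max(2, median + 3 * MAD)`` across subjects *and* strictly exceeds
    the median — so that a uniformly (un)successful cohort flags nobody.
    """
    truth = np.asarray(truth, dtype=int)
    counts = (report.votes.to_numpy() != truth[:, None]).sum(axis=1)
    med = np.median(counts)
    mad = np.median(np.abs(counts - med))
    cutoff = max(2.0, med + 3.0 * mad)
    return (counts >= cutoff) & (counts > med)
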
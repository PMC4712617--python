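"""Power study: minimised error-rate statistics versus the Mann-Whitney test.

The simulation design draws controls from a standard log-normal distribution,
``X = exp(Z)`` with ``Z ~ N(0, 1)``, and experimental subjects upwardly
shifted on the log scale, ``X = exp(Z + mu)``, for ``mu`` on a grid.  For
each repetition three p-values are computed: the upward-rule statistic
``er*_up`` and the direction-free ``er*_min`` against their simulated null
distributions, and the one-sided two-sample Mann-Whitney (rank-sum) test in
the direction of the upward alternative.

Two summaries are produced per grid point: the mean p-value of each statistic
(expected power), and the proportion of repetitions in which a competing
statistic's p-value falls below that of ``er*_up`` (above 50% means the
competitor is more often the better test at that shift).  The error-rate
p-values entering these comparisons are the raw simulated left-tail fractions
``#{null draws < observed}/M`` — the literal Monte-Carlo estimate, which can
reach 0 at complete separation and therefore compares the statistics on the
scale the null simulation actually resolves.

This module doubles as the package's synthetic fixture generator
(:func:`generate_dataset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import LabeledSample, Weights, batch_minimized_error_rates
from .nulldist import DEFAULT_SEED, simulate_null

__all__ = [
    "PowerSimConfig",
    "PowerSimResult",
    "generate_dataset",
    "run_power_sim",
    "crossover_shift",
]

#: grid of log-scale shifts covering the whole crossover region at step 0.2
DEFAULT_MU_GRID = tuple(np.round(np.arange(0.0, 4.0 + 1e-9, 0.2), 10))


@dataclass(frozen=True)
class PowerSimConfig:
    """Design of one power-comparison run.

    Defaults give the reference design: group sizes 21/12, shift grid 0 to 4
    in steps of 0.2, one-million-draw null distributions, and 2,000
    repetitions per grid point — the Monte-Carlo standard error of a
    proportion is then at most about 0.011.  Raise ``reps`` for smoother
    curves (the acceptance script runs 10,000).
    """

    n0: int = 21
    n1: int = 12
    mu_grid: tuple = DEFAULT_MU_GRID
    reps: int = 2_000
    weights: Weights = Weights()
    m_null: int = 1_000_000
    seed: int = DEFAULT_SEED
    mw_method: str = "asymptotic"

    def __post_init__(self) -> None:
        if any(mu < 0 for mu in self.mu_grid):
            raise ValueError("all shifts mu must be non-negative")
        if self.reps < 1:
            raise ValueError(f"reps must be at least 1, got {self.reps}")
        if self.mw_method not in ("asymptotic", "exact", "auto"):
            raise ValueError(f"unknown mw_method {self.mw_method!r}")


@dataclass
class PowerSimResult:
    """Mean-p and proportion-better curves per shift magnitude."""

    config: PowerSimConfig
    table: pd.DataFrame  # mu, mean_p_er_up, mean_p_er_min, mean_p_mw, prop_mw, prop_er_min

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (mu, statistic, mean_p, prop_better) for export."""
        rows = []
        for _, r in self.table.iterrows():
            rows.append((r.mu, "er_up", r.mean_p_er_up, np.nan))
            rows.append((r.mu, "er_min", r.mean_p_er_min, r.prop_er_min))
            rows.append((r.mu, "mw", r.mean_p_mw, r.prop_mw))
        return pd.DataFrame(rows, columns=["mu", "statistic", "mean_p", "prop_better"])

    def plot(self, path=None):
        """Mean-p and proportion-better panels (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
        t = self.table
        for col, label in [
            ("mean_p_er_up", "er*_up"),
            ("mean_p_er_min", "er*_min"),
            ("mean_p_mw", "MW"),
        ]:
            ax1.plot(t.mu, t[col], label=label)
        ax1.set_xlabel("shift mu"), ax1.set_ylabel("mean p-value"), ax1.legend()
        ax2.plot(t.mu, t.prop_mw, label="MW vs er*_up")
        ax2.plot(t.mu, t.prop_er_min, label="er*_min vs er*_up")
        ax2.axhline(0.5, color="red", ls=":")
        ax2.set_xlabel("shift mu"), ax2.set_ylabel("proportion better"), ax2.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def generate_dataset(n0: int, n1: int, mu: float, seed=DEFAULT_SEED) -> LabeledSample:
    """Synthetic two-group sample: log-normal controls, log-shifted experimentals.

    ``seed`` may be an integer or a ``numpy.random.Generator`` (so a stream
    can be shared across repetitions).
    """
    if mu < 0:
        raise ValueError(
            f"mu must be non-negative, got {mu}; obtain downward shifts by "
            "relabelling the groups (label-swap duality)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(n0 + n1)
    z[n0:] += mu
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return LabeledSample(np.exp(z), labels)


def _mw_method(config: PowerSimConfig) -> str:
    if config.mw_method != "auto":
        return config.mw_method
    return "exact" if min(config.n0, config.n1) < 25 else "asymptotic"


def run_power_sim(config: PowerSimConfig = PowerSimConfig()) -> PowerSimResult:
    """Run the full power comparison over the shift grid."""
    null_up = simulate_null(
        config.n0, config.n1, config.weights, "up", m=config.m_null, seed=config.seed
    )
    null_min = simulate_null(
        config.n0, config.n1, config.weights, "min", m=config.m_null, seed=config.seed + 1
    )
    rng = np.random.default_rng(config.seed + 2)
    labels = np.concatenate(
        [np.zeros(config.n0, dtype=int), np.ones(config.n1, dtype=int)]
    )
    method = _mw_method(config)
    rows = []
    for mu in config.mu_grid:
        x = np.vstack(
            [
                generate_dataset(config.n0, config.n1, mu, rng).values
                for _ in range(config.reps)
            ]
        )
        er_up = batch_minimized_error_rates(x, labels, config.weights, "up")
        er_min = batch_minimized_error_rates(x, labels, config.weights, "min")
        p_up = np.asarray(null_up.tail_fraction(er_up))
        p_min = np.asarray(null_min.tail_fraction(er_min))
        p_mw = stats.mannwhitneyu(
            x[:, config.n0 :],
            x[:, : config.n0],
            alternative="greater",
            method=method,
            axis=1,
        ).pvalue
        rows.append(
            (
                mu,
                p_up.mean(),
                p_min.mean(),
                p_mw.mean(),
                float((p_mw < p_up).mean()),
                float((p_min < p_up).mean()),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mu",
            "mean_p_er_up",
            "mean_p_er_min",
            "mean_p_mw",
            "prop_mw",
            "prop_er_min",
        ],
    )
    return PowerSimResult(config=config, table=table)


def crossover_shift(
    result: PowerSimResult, statistic: str = "mw", method: str = "interpolated"
) -> float | None:
    """Shift at which the competing statistic stops beating ``er*_up``.

    Locates the last downward crossing of 50% in the proportion-better curve
    (after which the curve stays below).  ``method="interpolated"`` (default)
    interpolates the crossing linearly between the bracketing grid points —
    the natural estimate of where a plotted curve cuts the 50% line and
    stable when the curve touches 0.5 at a grid point.  ``method="grid"``
    returns the first grid value of the sustained-below region.  Returns the
    first grid point if the curve never reaches 50%, and ``None`` if it never
    drops below.
    """
    col = {"mw": "prop_mw", "er_min": "prop_er_min"}.get(statistic)
    if col is None:
        raise ValueError(f"statistic must be 'mw' or 'er_min', got {statistic!r}")
    if method not in ("interpolated", "grid"):
        raise ValueError(f"method must be 'interpolated' or 'grid', got {method!r}")
    mus = result.table["mu"].to_numpy()
    prop = result.table[col].to_numpy()
    above = np.nonzero(prop >= 0.5)[0]
    if above.size == 0:
        return float(mus[0])
    i = above[-1]
    if i == mus.size - 1:
        return None
    if method == "grid":
        return float(mus[i + 1])
    return float(mus[i] + (mus[i + 1] - mus[i]) * (prop[i] - 0.5) / (prop[i] - prop[i + 1]))
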
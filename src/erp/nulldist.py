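"""Monte-Carlo null distribution of the minimised error-rate statistics.

Under the null hypothesis that both groups share one continuous distribution,
the minimised error rate depends on the data only through the ranks of the
observations, so its null distribution can be simulated once per
``(N0, N1, w0, w1, mode)`` and reused for every variable of a dataset:
generate ``N`` iid Uniform(0,1) variates, assign the first ``N0`` labels as
control, minimise the weighted error rate over the candidate cuts, and repeat
``M`` times.

Two tail-counting conventions are provided.  :meth:`NullDistribution.p_value`
uses inclusive counting with an add-one correction,
``p = (1 + #{draws <= obs}) / (M + 1)``, which is a valid p-value on the
discrete support (it can never be 0 and its type-I error is at most the
nominal level).  :meth:`NullDistribution.tail_fraction` returns the plain
strictly-below fraction ``#{draws < obs} / M``, the literal simulated
left-tail estimate used by the power-comparison study.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Mode, Weights, batch_minimized_error_rates

__all__ = [
    "NullDistribution",
    "simulate_null",
    "p_value",
    "null_cdf_quantile",
    "clear_cache",
    "DEFAULT_SEED",
    "DEFAULT_M",
]

DEFAULT_SEED = 20160114
DEFAULT_M = 100_000

#: floating tolerance absorbing round-off between equal lattice rationals
LATTICE_EPS = 1e-12

_CACHE: dict[tuple, "NullDistribution"] = {}

_SIM_BATCH = 200_000  # rows simulated per chunk, caps peak memory


@dataclass(frozen=True)
class NullDistribution:
    """Sorted Monte-Carlo draws of a minimised error-rate statistic under H0."""

    n0: int
    n1: int
    weights: Weights
    mode: Mode
    draws: np.ndarray
    seed: int

    @property
    def m(self) -> int:
        return int(self.draws.shape[0])

    @property
    def key(self) -> tuple:
        return (self.n0, self.n1, self.weights.w0, self.weights.w1, self.mode)

    def support_lattice(self) -> np.ndarray:
        """All values ``w0*j/n0 + w1*k/n1`` the statistic can take, sorted."""
        j = np.arange(self.n0 + 1)
        k = np.arange(self.n1 + 1)
        grid = (self.weights.w0 * j / self.n0)[:, None] + (
            self.weights.w1 * k / self.n1
        )[None, :]
        return np.unique(grid)

    def p_value(self, observed: float | np.ndarray) -> float | np.ndarray:
        """Valid p-value: ``(1 + #{draws <= observed}) / (M + 1)``."""
        observed = np.asarray(observed, dtype=float)
        if np.any(observed < 0) or np.any(observed > 1):
            raise ValueError("observed error rate must lie in [0, 1]")
        count = np.searchsorted(self.draws, observed + LATTICE_EPS, side="right")
        p = (1.0 + count) / (self.m + 1.0)
        return float(p) if p.ndim == 0 else p

    def tail_fraction(self, observed: float | np.ndarray) -> float | np.ndarray:
        """Raw strictly-below left-tail fraction ``#{draws < observed} / M``."""
        observed = np.asarray(observed, dtype=float)
        count = np.searchsorted(self.draws, observed - LATTICE_EPS, side="left")
        frac = count / self.m
        return float(frac) if frac.ndim == 0 else frac

    def critical_value(self, alpha: float) -> float | None:
        """Largest support value whose p-value is at most ``alpha``.

        Returns ``None`` when no support value qualifies (possible for tiny
        groups where even a zero error rate is too likely under H0).
        """
        if not 0.0 < alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
        lattice = self.support_lattice()
        ok = lattice[self.p_value(lattice) <= alpha]
        return float(ok.max()) if ok.size else None

    def save(self, path: str | Path) -> None:
        """Persist sorted draws as a one-column CSV with the key in the header."""
        path = Path(path)
        header = (
            f"er_star,n0={self.n0},n1={self.n1},w0={self.weights.w0!r},"
            f"w1={self.weights.w1!r},mode={self.mode},m={self.m},seed={self.seed}"
        )
        np.savetxt(path, self.draws, fmt="%.17g", header=header, comments="# ")

    @classmethod
    def load(cls, path: str | Path) -> "NullDistribution":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=") for item in header.split(",")[1:])
        draws = np.sort(np.loadtxt(path))
        return cls(
            n0=int(meta["n0"]),
            n1=int(meta["n1"]),
            weights=Weights(float(meta["w0"]), float(meta["w1"])),
            mode=meta["mode"],  # type: ignore[arg-type]
            draws=draws,
            seed=int(meta["seed"]),
        )


def simulate_null(
    n0: int,
    n1: int,
    weights: Weights = Weights(),
    mode: Mode = "up",
    m: int = DEFAULT_M,
    seed: int = DEFAULT_SEED,
    *,
    cache: bool = True,
) -> NullDistribution:
    """Simulate ``m`` iid draws of the minimised statistic under H0.

    Results are memoised on ``(n0, n1, w0, w1, mode, m, seed)`` because every
    variable of one dataset shares a single null distribution.
    """
    if n0 < 1 or n1 < 1:
        raise ValueError(f"group sizes must be at least 1, got n0={n0}, n1={n1}")
    if m < 1:
        raise ValueError(f"m must be at least 1, got {m}")
    key = (n0, n1, weights.w0, weights.w1, mode, m, seed)
    if cache and key in _CACHE:
        return _CACHE[key]
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    chunks = []
    remaining = m
    while remaining > 0:
        rows = min(_SIM_BATCH, remaining)
        u = rng.random((rows, n0 + n1))
        chunks.append(batch_minimized_error_rates(u, labels, weights, mode))
        remaining -= rows
    null = NullDistribution(
        n0=n0,
        n1=n1,
        weights=weights,
        mode=mode,
        draws=np.sort(np.concatenate(chunks)),
        seed=seed,
    )
    if cache:
        _CACHE[key] = null
    return null


def p_value(null: NullDistribution, observed: float) -> float:
    """Functional form of :meth:`NullDistribution.p_value`."""
    return float(null.p_value(observed))


def null_cdf_quantile(null: NullDistribution, alpha: float) -> float | None:
    """Critical error rate at level ``alpha``; see :meth:`critical_value`."""
    return null.critical_value(alpha)


def clear_cache() -> None:
    _CACHE.clear()
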
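"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's EM code path: the grid
oracle scores the multinomial likelihood over a dense simplex grid, and the
optimizer oracle runs a constrained numerical maximization with scipy. Both
exist so EM results can be checked against an implementation-independent
maximum.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from rarephase.pairmodel import PairGenotypeCounts, hwe_genotype_probs


def simplex_grid(step: float) -> np.ndarray:
    """All frequency vectors (f_AB, f_Ab, f_aB, f_ab) on a simplex lattice."""
    m = int(round(1.0 / step))
    i, j, k = np.meshgrid(np.arange(m + 1), np.arange(m + 1), np.arange(m + 1),
                          indexing="ij")
    s = i + j + k
    keep = s <= m
    i, j, k = i[keep], j[keep], k[keep]
    grid = np.column_stack([i, j, k, m - i - j - k]).astype(np.float64) / m
    return grid


class GridOracle:
    """Dense-grid maximizer of the 9-class multinomial log-likelihood."""

    def __init__(self, step: float = 0.005) -> None:
        self.step = step
        grid = simplex_grid(step)
        probs = np.empty((len(grid), 9))
        f_AB, f_Ab, f_aB, f_ab = grid.T
        probs[:, 0] = f_AB ** 2            # AABB
        probs[:, 1] = 2 * f_AB * f_aB      # AaBB
        probs[:, 2] = f_aB ** 2            # aaBB
        probs[:, 3] = 2 * f_AB * f_Ab      # AABb
        probs[:, 4] = 2 * f_AB * f_ab + 2 * f_Ab * f_aB  # AaBb
        probs[:, 5] = 2 * f_aB * f_ab      # aaBb
        probs[:, 6] = f_Ab ** 2            # AAbb
        probs[:, 7] = 2 * f_Ab * f_ab      # Aabb
        probs[:, 8] = f_ab ** 2            # aabb
        with np.errstate(divide="ignore"):
            self.logprobs = np.log(probs)
        # a zero-probability class with observed counts must lose the argmax
        self.logprobs[np.isneginf(self.logprobs)] = -1e30
        self.grid = grid

    def counts_vector(self, counts: PairGenotypeCounts) -> np.ndarray:
        t = counts.table
        return np.array([t[0, 0], t[1, 0], t[2, 0], t[0, 1], t[1, 1],
                         t[2, 1], t[0, 2], t[1, 2], t[2, 2]], dtype=float)

    def max_loglike(self, counts: PairGenotypeCounts) -> float:
        scores = self.logprobs @ self.counts_vector(counts)
        return float(scores.max())

    def argmax(self, counts: PairGenotypeCounts) -> np.ndarray:
        scores = self.logprobs @ self.counts_vector(counts)
        return self.grid[int(scores.argmax())]


@pytest.fixture(scope="session")
def grid_oracle() -> GridOracle:
    return GridOracle(step=0.005)


def loglike_direct(counts: PairGenotypeCounts, freqs: np.ndarray) -> float:
    """Straight multinomial log-likelihood, written independently of the model."""
    probs = hwe_genotype_probs(np.asarray(freqs, dtype=float))
    t = counts.table
    mask = t > 0
    if np.any(probs[mask] <= 0):
        return -np.inf
    return float((t[mask] * np.log(probs[mask])).sum())


def optimizer_mle(counts: PairGenotypeCounts) -> tuple[np.ndarray, float]:
    """Constrained numerical MLE over the frequency simplex (SLSQP, multistart)."""
    starts = [
        np.full(4, 0.25),
        np.array([0.7, 0.1, 0.1, 0.1]),
        np.array([0.1, 0.4, 0.4, 0.1]),
        np.array([0.4, 0.1, 0.1, 0.4]),
    ]
    best_f, best_ll = None, -np.inf
    eps = 1e-12

    def neg_ll(f):
        f = np.clip(f, eps, 1.0)
        probs = hwe_genotype_probs(f)
        t = counts.table
        mask = t > 0
        return -float((t[mask] * np.log(np.maximum(probs[mask], 1e-300))).sum())

    for x0 in starts:
        res = minimize(neg_ll, x0, method="SLSQP",
                       bounds=[(0.0, 1.0)] * 4,
                       constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
                       options={"maxiter": 500, "ftol": 1e-12})
        f = np.clip(res.x, 0.0, 1.0)
        f = f / f.sum()
        ll = loglike_direct(counts, f)
        if ll > best_ll:
            best_f, best_ll = f, ll
    return best_f, best_ll


def random_tables(rng: np.random.Generator, n_tables: int,
                  max_n: int = 50) -> list[PairGenotypeCounts]:
    """Random non-degenerate 3x3 genotype tables with n_total <= max_n."""
    tables = []
    while len(tables) < n_tables:
        n = int(rng.integers(1, max_n + 1))
        probs = rng.dirichlet(np.full(9, rng.choice([0.3, 1.0, 3.0])))
        t = rng.multinomial(n, probs).reshape(3, 3)
        tables.append(PairGenotypeCounts(t))
    return tables
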
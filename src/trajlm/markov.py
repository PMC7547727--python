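"""Stationary first-order Markov chains with closed-form references.

These are the controlled sources used to validate every statistical claim
the LSTM makes: a chain with a known transition matrix has an analytic
stationary law, entropy rate, and mean-first-passage commute times, so the
model's per-symbol loss, learned conditional rows, and kinetic distances
can all be checked against exact values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MarkovChainSpec", "sample_chain", "stationary_distribution",
    "entropy_rate", "ml_transition_estimate", "mfpt", "mfpt_commute",
]


@dataclass(frozen=True)
class MarkovChainSpec:
    """An irreducible finite chain to sample from; rows of the transition
    matrix must sum to 1."""

    transition_matrix: np.ndarray
    length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.transition_matrix, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(p < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition-matrix rows must sum to 1")
        n, _ = connected_components(csgraph=(p > 0), directed=True,
                                    connection="strong")
        if n != 1:
            raise ValueError("transition matrix is reducible")
        object.__setattr__(self, "transition_matrix", p)
        if self.length < 1:
            raise ValueError("length must be >= 1")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    """Stationary vector via the leading left eigenvector, renormalized."""
    p = np.asarray(p, dtype=float)
    w, v = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_chain(spec: MarkovChainSpec) -> np.ndarray:
    """Draw a realization, starting from the stationary distribution."""
    p = spec.transition_matrix
    rng = np.random.default_rng(spec.seed)
    pi = stationary_distribution(p)
    cdf = np.cumsum(p, axis=1)
    out = np.empty(spec.length, dtype=np.int64)
    u = rng.random(spec.length)
    state = int(np.searchsorted(np.cumsum(pi), u[0] * pi.sum(), side="right"))
    state = min(state, spec.n_states - 1)
    out[0] = state
    for t in range(1, spec.length):
        state = int(np.searchsorted(cdf[state], u[t] * cdf[state, -1],
                                    side="right"))
        state = min(state, spec.n_states - 1)
        out[t] = state
    return out


def entropy_rate(spec: MarkovChainSpec | np.ndarray) -> float:
    """Entropy rate -sum_i pi_i sum_j P_ij ln P_ij in nats per symbol —
    the floor of achievable per-symbol cross-entropy."""
    p = spec.transition_matrix if isinstance(spec, MarkovChainSpec) \
        else np.asarray(spec, dtype=float)
    pi = stationary_distribution(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(-(pi @ plogp.sum(axis=1)))


def ml_transition_estimate(labels, n_states: int) -> np.ndarray:
    """Row-normalized transition counts (maximum-likelihood estimate).

    A state never departed from yields a NaN row rather than an error."""
    labels = np.asarray(getattr(labels, "labels", labels), dtype=np.int64)
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (labels[:-1], labels[1:]), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = counts / rowsum
    est[rowsum[:, 0] == 0] = np.nan
    return est


def mfpt(p: np.ndarray) -> np.ndarray:
    """Mean first-passage times M[i, j] = E[steps to first hit j from i],
    by solving M[i, j] = 1 + sum_{k != j} P_ik M[k, j] per target."""
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        others = [i for i in range(n) if i != j]
        a = np.eye(n - 1) - p[np.ix_(others, others)]
        m = np.linalg.solve(a, np.ones(n - 1))
        out[others, j] = m
    return out


def mfpt_commute(spec: MarkovChainSpec | np.ndarray) -> dict[tuple[int, int], float]:
    """Round-trip commute times MFPT(l->m) + MFPT(m->l) per unordered pair."""
    p = spec.transition_matrix if isinstance(spec, MarkovChainSpec) \
        else np.asarray(spec, dtype=float)
    m = mfpt(p)
    n = p.shape[0]
    return {(l, k): float(m[l, k] + m[k, l])
            for l in range(n) for k in range(l + 1, n)}
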
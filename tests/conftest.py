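"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use naive algorithms (exhaustive search,
direct enumeration) so they share no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ploidyshift.synthetic import balanced_tree, simulate_coalescent_tree


@pytest.fixture(scope="session")
def tree32():
    """32-tip balanced unit-height tree for OU experiments."""
    return balanced_tree(depth=5)


@pytest.fixture(scope="session")
def tree4():
    """Small random ultrametric tree."""
    return simulate_coalescent_tree(4, seed=42)


def exact_chromatic_number(edges: list[tuple[int, int]], n: int) -> int:
    """Brute-force chromatic number: try k = 1..n colorings exhaustively.

    Independent of the package's coloring code: plain recursive
    enumeration over nodes in index order.
    """
    adj = [set() for _ in range(n)]
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def colorable(k: int) -> bool:
        colors = [-1] * n

        def place(i: int) -> bool:
            if i == n:
                return True
            banned = {colors[j] for j in adj[i] if colors[j] >= 0}
            for c in range(k):
                if c not in banned:
                    colors[i] = c
                    if place(i + 1):
                        return True
                    colors[i] = -1
                if c not in banned and all(colors[j] < 0 for j in range(i)):
                    break
            return False

        return place(0)

    for k in range(1, n + 1):
        if colorable(k):
            return k
    return n


def gmm_loglik(x: np.ndarray, mu, sigma, lam) -> float:
    """Direct mixture log-likelihood, written independently of the EM code."""
    x = np.asarray(x)[:, None]
    mu = np.asarray(mu)[None, :]
    sigma = np.asarray(sigma)[None, :]
    lam = np.asarray(lam)[None, :]
    dens = lam * np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (np.sqrt(2 * np.pi) * sigma)
    return float(np.sum(np.log(dens.sum(axis=1))))


def shift_hit(model, edge: int) -> bool:
    """True if the model selected ``edge`` or a likelihood-equivalent twin."""
    if edge in model.shift_edges:
        return True
    return any(edge in model.equivalent_edges.get(x, ()) for x in model.shift_edges)
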
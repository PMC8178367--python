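"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written by a different route than the package
(exhaustive enumeration, closed-form combinatorics, numeric integration of
textbook densities) so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

from scipy.integrate import quad


def connected_subsets(n_nodes: int, edges: list[tuple[int, int]]):
    """Yield every non-empty connected subset of nodes 0..n-1 (bitmask BFS)."""
    adj_mask = [0] * n_nodes
    for u, v in edges:
        adj_mask[u] |= 1 << v
        adj_mask[v] |= 1 << u
    for size in range(1, n_nodes + 1):
        for combo in itertools.combinations(range(n_nodes), size):
            mask = 0
            for i in combo:
                mask |= 1 << i
            # flood fill from the first member
            seen = 1 << combo[0]
            frontier = seen
            while frontier:
                nxt = 0
                f = frontier
                while f:
                    low = f & -f
                    nxt |= adj_mask[low.bit_length() - 1] & mask & ~seen
                    f ^= low
                seen |= nxt
                frontier = nxt
            if seen == mask:
                yield combo


def brute_force_best_subgraph(
    scores: list[float], edges: list[tuple[int, int]], weights: list[float] | None = None
) -> tuple[tuple[int, ...], float]:
    """Exhaustive maximum of sum(w s)/sqrt(sum w^2) over connected subsets."""
    n = len(scores)
    w = [1.0] * n if weights is None else list(weights)
    best: tuple[tuple[int, ...], float] = ((), -math.inf)
    for combo in connected_subsets(n, edges):
        num = sum(w[i] * scores[i] for i in combo)
        den = math.sqrt(sum(w[i] ** 2 for i in combo))
        z = num / den
        if z > best[1] or (z == best[1] and combo < best[0]):
            best = (combo, z)
    return best


def t_sf_numeric(t: float, df: int) -> float:
    """Upper tail of Student's t by numeric integration of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(pdf, t, math.inf)
    return val


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact comb enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total
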
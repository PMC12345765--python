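"""Independent grid-search oracle for the Cox partial likelihood.

Evaluates the Efron-approximation log partial likelihood on a dense beta
grid and returns the maximizer — a brute-force check kept deliberately
separate from the fitting route the package uses.
"""

from __future__ import annotations

import numpy as np


def efron_log_partial_likelihood(
    beta: np.ndarray, x: np.ndarray, times: np.ndarray, events: np.ndarray
) -> np.ndarray:
    """Efron-tie log partial likelihood, vectorized over a beta grid."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    xb = np.outer(beta, x)          # (B, n)
    exb = np.exp(xb)
    ll = np.zeros(len(beta))
    for tau in np.unique(times[events == 1]):
        dead = (times == tau) & (events == 1)
        at_risk = times >= tau
        m = int(dead.sum())
        ll += xb[:, dead].sum(axis=1)
        sum_risk = exb[:, at_risk].sum(axis=1)
        sum_dead = exb[:, dead].sum(axis=1)
        for ell in range(m):
            ll -= np.log(sum_risk - (ell / m) * sum_dead)
    return ll


def grid_search_beta(
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    lo: float = -5.0,
    hi: float = 5.0,
    step: float = 1e-4,
) -> float:
    """Maximizer of the Efron partial likelihood over a [lo, hi] grid."""
    grid = np.arange(lo, hi + step / 2, step)
    ll = efron_log_partial_likelihood(grid, x, times, events)
    return float(grid[int(np.argmax(ll))])


def brute_force_cascade(
    universe: list[str],
    start: set[str],
    steps: list[tuple[str, set[str]]],
) -> set[str]:
    """Per-element membership evaluation of a subtract/intersect cascade."""
    final = set()
    for element in universe:
        keep = element in start
        for kind, ref in steps:
            if kind == "subtract":
                keep = keep and element not in ref
            else:  # intersect / subfunction
                keep = keep and element in ref
        if keep:
            final.add(element)
    return final
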
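"""Independent brute-force oracles used by the unit and acceptance tests."""

import numpy as np

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def enumerate_optimal_action(energies, start, end, mode="integral"):
    """Exhaustive optimal path value over all simple 8-connected paths.

    Depth-first enumeration with branch-and-bound pruning (a partial path is
    abandoned once its cost provably exceeds the best complete path found so
    far; with nonnegative costs this discards only suboptimal prefixes, so the
    search remains exhaustive).  Returns the optimal value: the integral
    action, or for ``mode="minimax"`` the lexicographic (max energy, integral)
    pair.  Returns None if no path exists.
    """
    energies = np.asarray(energies, dtype=float)
    n1, n2 = energies.shape
    passable = ~np.isnan(energies)
    start, end = tuple(start), tuple(end)
    if not (passable[start] and passable[end]):
        return None
    best = [None]
    visited = np.zeros_like(passable)

    def step_cost(a, b):
        return float(np.hypot(a[0] - b[0], a[1] - b[1])) * 0.5 * (
            energies[a] + energies[b]
        )

    def key(maxe, integ):
        return (maxe, integ) if mode == "minimax" else (integ,)

    def dfs(cell, maxe, integ):
        if best[0] is not None and key(maxe, integ) >= best[0]:
            return
        if cell == end:
            best[0] = key(maxe, integ)
            return
        visited[cell] = True
        for di, dj in _NEIGHBORS:
            nb = (cell[0] + di, cell[1] + dj)
            if not (0 <= nb[0] < n1 and 0 <= nb[1] < n2):
                continue
            if visited[nb] or not passable[nb]:
                continue
            dfs(nb, max(maxe, energies[nb]), integ + step_cost(cell, nb))
        visited[cell] = False

    dfs(start, energies[start], 0.0)
    return best[0]


def random_masked_energies(rng, n1, n2, mask_prob=0.2, emax=5.0):
    """A random energy grid with NaN-masked cells, min energy 0 on unmasked."""
    e = rng.random((n1, n2)) * emax
    mask = rng.random((n1, n2)) < mask_prob
    e[mask] = np.nan
    if np.isnan(e).all():
        e[0, 0] = 1.0
    e -= np.nanmin(e)
    return e
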
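"""Independent oracles shared by the test suite.

The simplex grid enumerator is the brute-force reference for the inner
donor-weight quadratic programme: it exhaustively evaluates the
objective on every point of the weight simplex at a fixed resolution.
It is deliberately independent of the solver implementation.
"""

import numpy as np


def simplex_grid(n_parts: int, step: float = 0.005) -> np.ndarray:
    """All points of the (n_parts)-simplex with coordinates on a grid
    of the given step (exhaustive composition enumeration)."""
    m = round(1.0 / step)
    if n_parts == 1:
        return np.array([[1.0]])
    a = np.arange(m + 1, dtype=np.int32)
    if n_parts == 2:
        first = a[:, None]
        grid = np.hstack([first, m - first])
    else:
        axes = np.meshgrid(*([a] * (n_parts - 1)), indexing="ij", sparse=True)
        total = sum(axes)
        mask = total <= m
        firsts = np.stack([np.broadcast_to(ax, total.shape)[mask] for ax in axes], axis=1)
        grid = np.hstack([firsts, (m - total[mask])[:, None]])
    return grid.astype(np.float64) * step


def grid_search_objective(x_treated: np.ndarray, x_donors: np.ndarray,
                          v: np.ndarray, step: float = 0.005) -> float:
    """Minimum of (x1 - X0 w)' diag(v) (x1 - X0 w) over the gridded
    simplex; evaluated in chunks to bound memory."""
    W = simplex_grid(x_donors.shape[1], step)
    best = np.inf
    for chunk in np.array_split(W, max(1, len(W) // 500_000)):
        resid = x_treated[None, :] - chunk @ x_donors.T
        vals = (resid**2 * v[None, :]).sum(axis=1)
        best = min(best, float(vals.min()))
    return best
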
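"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def recovery_grid_oracle(signals, tr_ms, t1_bounds=(0.05, 5.0), step=1e-3, m0_span=(0.3, 4.0)):
    """Exhaustive 2-D grid search for the saturation-recovery least squares.

    Grids are multiplicative with resolution ``step`` (0.1%).  For each T1
    column the SSE is an exact quadratic in M0, so the column minimum over
    the discrete M0 grid sits at one of the two grid points bracketing the
    continuous vertex; evaluating just those reproduces the full-grid
    argmin exactly while staying fast.  ``brute=True`` materialises the
    whole SSE surface instead (for cross-checking the shortcut).
    """
    signals = np.asarray(signals, dtype=np.float64)
    tr_s = np.asarray(tr_ms, dtype=np.float64) / 1000.0
    t1_grid = np.geomspace(t1_bounds[0], t1_bounds[1], int(np.log(t1_bounds[1] / t1_bounds[0]) / step) + 1)
    smax = float(signals.max())
    m0_grid = np.geomspace(m0_span[0] * smax, m0_span[1] * smax, int(np.log(m0_span[1] / m0_span[0]) / step) + 1)

    f = 1.0 - np.exp(-tr_s[:, None] / t1_grid[None, :])  # (n_tr, n_t1)
    sf = signals @ f
    ff = np.sum(f * f, axis=0)
    ss = float(signals @ signals)

    # per-column vertex of the quadratic SSE(m0) = ss - 2 m0 sf + m0^2 ff
    vertex = np.clip(sf / ff, m0_grid[0], m0_grid[-1])
    hi_idx = np.clip(np.searchsorted(m0_grid, vertex), 1, len(m0_grid) - 1)
    candidates = np.stack([m0_grid[hi_idx - 1], m0_grid[hi_idx]], axis=0)  # (2, n_t1)
    sse = ss - 2.0 * candidates * sf[None, :] + candidates**2 * ff[None, :]
    best_of_two = np.argmin(sse, axis=0)
    cols = np.arange(len(t1_grid))
    col_min = sse[best_of_two, cols]
    j = int(np.argmin(col_min))
    m0_best = candidates[best_of_two[j], j]

    # profiled variant: exact (continuous) M0 per column.  The discrete-M0
    # argmin above carries quantisation tie noise of up to ~2 T1 steps in
    # flat stretches of the valley; the profiled argmin is tie-noise free
    # and is the right reference for one-step parameter agreement.
    profile = ss - np.clip(sf, 0.0, None) ** 2 / ff
    j_prof = int(np.argmin(profile))
    result = {
        "m0": float(m0_best),
        "t1": float(t1_grid[j]),
        "sse_min": float(col_min[j]),
        "t1_profiled": float(t1_grid[j_prof]),
        "m0_profiled": float(np.clip(sf[j_prof] / ff[j_prof], 0.0, None)),
        "t1_grid": t1_grid,
        "m0_grid": m0_grid,
    }
    return result


def recovery_grid_oracle_brute(signals, tr_ms, t1_bounds=(0.05, 5.0), step=1e-3, m0_span=(0.3, 4.0)):
    """Literal full-surface variant of :func:`recovery_grid_oracle`."""
    signals = np.asarray(signals, dtype=np.float64)
    tr_s = np.asarray(tr_ms, dtype=np.float64) / 1000.0
    t1_grid = np.geomspace(t1_bounds[0], t1_bounds[1], int(np.log(t1_bounds[1] / t1_bounds[0]) / step) + 1)
    smax = float(signals.max())
    m0_grid = np.geomspace(m0_span[0] * smax, m0_span[1] * smax, int(np.log(m0_span[1] / m0_span[0]) / step) + 1)
    f = 1.0 - np.exp(-tr_s[:, None] / t1_grid[None, :])
    sf = signals @ f
    ff = np.sum(f * f, axis=0)
    ss = float(signals @ signals)
    sse = ss - 2.0 * np.outer(m0_grid, sf) + np.outer(m0_grid**2, ff)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(m0_grid[i]), float(t1_grid[j]), float(sse[i, j])


def recovery_sse(signals, tr_ms, m0, t1_s):
    signals = np.asarray(signals, dtype=np.float64)
    tr_s = np.asarray(tr_ms, dtype=np.float64) / 1000.0
    return float(np.sum((signals - m0 * (1.0 - np.exp(-tr_s / t1_s))) ** 2))


def grid_index(grid, value):
    """Index of the grid point nearest to ``value`` (log metric)."""
    return int(np.argmin(np.abs(np.log(grid) - np.log(value))))
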
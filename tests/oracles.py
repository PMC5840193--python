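"""Independent oracles used to validate the combinatorial machinery.

The body-bar pebble game is checked against linear algebra: a generic
rigidity matrix is assembled with random bar attachment points, its rank
gives the number of independent constraints (so ``6|V| - rank`` free
pebbles), and the dimension of the null space projected onto a body
subset's coordinates gives the subgraph DOF count.  These stay deliberately
independent of the pebble-game code path.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space


def _rank(a: np.ndarray) -> int:
    """Numerical rank with a relative 1e-8 cutoff.

    Generic rigidity matrices have O(1) singular values with a wide gap at
    the rank boundary; the default machine-precision tolerance of
    ``matrix_rank`` occasionally miscounts borderline ~1e-14 values.
    """
    if a.size == 0:
        return 0
    sv = np.linalg.svd(a, compute_uv=False)
    return int(np.sum(sv > 1e-8 * sv[0]))


def rigidity_matrix(n_bodies: int, edges, rng: np.random.Generator) -> np.ndarray:
    """Generic body-bar rigidity matrix, one row per bar.

    Body motion is (v, w) in R^6; a bar attached at generic points p_u, p_v
    with direction d = p_v - p_u contributes the row
    ``d . (v_u + w_u x p_u) - d . (v_v + w_v x p_v) = 0``.
    """
    rows = []
    for u, v, bars in edges:
        for _ in range(bars):
            pu = rng.standard_normal(3)
            pv = rng.standard_normal(3)
            d = pv - pu
            row = np.zeros(6 * n_bodies)
            row[6 * u : 6 * u + 3] = d
            row[6 * u + 3 : 6 * u + 6] = np.cross(pu, d)
            row[6 * v : 6 * v + 3] = -d
            row[6 * v + 3 : 6 * v + 6] = -np.cross(pv, d)
            rows.append(row)
    if not rows:
        return np.zeros((0, 6 * n_bodies))
    return np.array(rows)


def dof_total_oracle(n_bodies: int, edges, rng: np.random.Generator) -> int:
    r = rigidity_matrix(n_bodies, edges, rng)
    rank = _rank(r)
    return 6 * n_bodies - rank


def dof_subset_oracle(n_bodies: int, edges, targets, rng: np.random.Generator) -> int:
    r = rigidity_matrix(n_bodies, edges, rng)
    ns = null_space(r) if r.size else np.eye(6 * n_bodies)
    idx = np.concatenate([np.arange(6 * t, 6 * t + 6) for t in targets])
    return _rank(ns[idx])


def random_multigraph(rng: np.random.Generator, max_bodies: int = 12, max_bars: int = 40):
    """A random body-bar multigraph within the given size bounds."""
    n = int(rng.integers(1, max_bodies + 1))
    m = int(rng.integers(0, max_bars + 1))
    edges = []
    total = 0
    while total < m and n >= 2:
        u, v = (int(x) for x in rng.integers(0, n, 2))
        if u == v:
            continue
        bars = min(int(rng.integers(1, 7)), m - total)
        edges.append((u, v, bars))
        total += bars
    return n, edges
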
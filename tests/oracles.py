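"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and the vectorized tricks) of the
package itself: plain flood fill, all-pairs adjacency scans, and exhaustive
contingency-table enumeration.
"""

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected components of a 3D boolean mask by explicit BFS flood fill."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                   (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3)
                   if o != (0, 0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and 0 <= nk < mask.shape[2]
                        and mask[ni, nj, nk] and not labels[ni, nj, nk]):
                    labels[ni, nj, nk] = current
                    stack.append((ni, nj, nk))
    return labels


def all_pairs_interface(labels: np.ndarray):
    """Interface voxel mask and sorted label-pair list by explicit 6-adjacency
    scan over every voxel."""
    interface = np.zeros(labels.shape, dtype=bool)
    pairs = []
    offsets = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for i in range(labels.shape[0]):
        for j in range(labels.shape[1]):
            for k in range(labels.shape[2]):
                a = labels[i, j, k]
                if a == 0:
                    continue
                for di, dj, dk in offsets:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (ni < labels.shape[0] and nj < labels.shape[1]
                            and nk < labels.shape[2]):
                        b = labels[ni, nj, nk]
                        if b > 0 and b != a:
                            interface[i, j, k] = True
                            interface[ni, nj, nk] = True
                            pairs.append(tuple(sorted((int(a), int(b)))))
    return interface, sorted(pairs)


def brute_force_fisher(table: np.ndarray) -> float:
    """Two-sided Fisher p by exhaustive iteration over every nonnegative
    integer matrix with the observed margins (itertools over all cells)."""
    import math

    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = table.sum()

    def prob(t):
        # multivariate hypergeometric probability of a fixed-margin table
        logp = (sum(math.lgamma(r + 1) for r in rows)
                + sum(math.lgamma(c + 1) for c in cols)
                - math.lgamma(N + 1)
                - sum(math.lgamma(v + 1) for v in np.ravel(t)))
        return math.exp(logp)

    p_obs = prob(table)
    total = 0.0
    r, c = table.shape
    ranges = [range(int(min(rows[i], cols[j])) + 1)
              for i in range(r) for j in range(c)]
    for cells in itertools.product(*ranges):
        t = np.array(cells).reshape(r, c)
        if (t.sum(axis=1) == rows).all() and (t.sum(axis=0) == cols).all():
            p = prob(t)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return min(total, 1.0)


def random_label_grid(rng: np.random.Generator, max_side: int = 20,
                      n_labels: int = 3, p_bone: float = 0.5) -> np.ndarray:
    shape = tuple(rng.integers(3, max_side + 1, size=3))
    grid = rng.integers(1, n_labels + 1, size=shape).astype(np.int16)
    grid[rng.random(shape) > p_bone] = 0
    return grid
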
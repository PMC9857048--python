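"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by the most literal method available
(flood fill, pair enumeration, exhaustive permutation) so that the package
implementations are checked against code that shares none of their logic.
"""

from collections import deque
from itertools import combinations, product

import numpy as np

#: All 26 neighbor offsets in 3D.
OFFSETS_26 = [off for off in product((-1, 0, 1), repeat=3) if off != (0, 0, 0)]


def flood_fill_26(values: np.ndarray, start: tuple[int, int, int], threshold: float) -> np.ndarray:
    """Boolean mask of the 26-connected component >= threshold containing start."""
    mask = np.zeros(values.shape, dtype=bool)
    if values[start] < threshold:
        return mask
    mask[start] = True
    queue = deque([start])
    shape = values.shape
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in OFFSETS_26:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if not mask[nx, ny, nz] and values[nx, ny, nz] >= threshold:
                    mask[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
    return mask


def auc_pairwise(metric, is_pos) -> float:
    """AUC as the mean concordance over all (positive, negative) pairs.

    The classifier score is -metric (low values predict the positive class).
    """
    metric = np.asarray(metric, float)
    is_pos = np.asarray(is_pos, bool)
    pos = metric[is_pos]
    neg = metric[~is_pos]
    total = 0.0
    for p in pos:
        for n in neg:
            if p < n:  # score -p > -n
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def midranks(values) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mid-rank."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of mid-ranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _u_statistic(a, b) -> float:
    """Mann-Whitney U of sample a vs b by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group labelings.

    Returns (U of sample a, p).  Two-sided p is the fraction of labelings
    whose U is at least as far from the null mean n_a*n_b/2 as observed.
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n_a = len(a)
    u_obs = _u_statistic(a, b)
    center = n_a * len(b) / 2.0
    extreme = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        sel = set(idx)
        ga = [pooled[i] for i in sel]
        gb = [pooled[i] for i in range(len(pooled)) if i not in sel]
        u = _u_statistic(ga, gb)
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
        total += 1
    return u_obs, extreme / total


def paired_t_formula(pre, post) -> float:
    """Textbook paired t statistic: mean difference over its standard error."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    n = len(d)
    sd = np.sqrt(((d - d.mean()) ** 2).sum() / (n - 1))
    return float(d.mean() / (sd / np.sqrt(n)))
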
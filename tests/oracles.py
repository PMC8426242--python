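"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity from first principles (flood fill,
exhaustive enumeration, grid search, O(n^2) double loops) without
touching the implementation code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a 3-D boolean grid by BFS flood fill."""
    if connectivity == 26:
        neigh = [off for off in itertools.product((-1, 0, 1), repeat=3)
                 if off != (0, 0, 0)]
    elif connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError(connectivity)
    remaining = {tuple(v) for v in np.argwhere(binary)}
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            cur = frontier.pop()
            for off in neigh:
                nxt = (cur[0] + off[0], cur[1] + off[1], cur[2] + off[2])
                if nxt in remaining:
                    remaining.remove(nxt)
                    comp.add(nxt)
                    frontier.append(nxt)
        components.append(comp)
    return components


def half_max_region(data: np.ndarray, seed_voxel: tuple[int, int, int],
                    half: float, connectivity: int = 26) -> set:
    """Voxels >= half connected to seed_voxel, by flood fill."""
    comps = flood_fill_components(data >= half, connectivity)
    for comp in comps:
        if tuple(seed_voxel) in comp:
            return comp
    return set()


def suv_peak_exhaustive(data: np.ndarray, spacing, focus_voxels,
                        sphere_volume_ml: float = 1.0) -> float:
    """SUVpeak by explicit distance checks over the whole grid for every
    candidate centre (candidate centres = focus voxels)."""
    r = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    best = -np.inf
    shape = data.shape
    for cx, cy, cz in focus_voxels:
        vals = []
        for ix in range(shape[0]):
            for iy in range(shape[1]):
                for iz in range(shape[2]):
                    d2 = (((ix - cx) * spacing[0]) ** 2
                          + ((iy - cy) * spacing[1]) ** 2
                          + ((iz - cz) * spacing[2]) ** 2)
                    if d2 <= r * r:
                        vals.append(data[ix, iy, iz])
        best = max(best, float(np.mean(vals)))
    return best


def cox_partial_loglik(beta: float, time, event, x) -> float:
    """Cox partial log-likelihood for one covariate, no ties (Breslow=Efron)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_argmax(time, event, x, lo=-5.0, hi=5.0, steps=2001) -> float:
    """Grid-search maximiser of the one-covariate partial likelihood
    (coarse scan, then a fine scan around the coarse argmax)."""
    grid = np.linspace(lo, hi, steps)
    vals = [cox_partial_loglik(b, time, event, x) for b in grid]
    centre = grid[int(np.argmax(vals))]
    width = (hi - lo) / (steps - 1)
    fine = np.linspace(centre - 2 * width, centre + 2 * width, 4001)
    fvals = [cox_partial_loglik(b, time, event, x) for b in fine]
    return float(fine[int(np.argmax(fvals))])


def cpe_double_loop(eta) -> float:
    """Gonen-Heller CPE by explicit O(n^2) loop over ordered pairs."""
    eta = np.asarray(eta, float)
    n = eta.size
    total = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = eta[i] - eta[j]
            if d == 0:
                total += 0.5
            else:
                total += 1.0 / (1.0 + math.exp(-abs(d)))
            npairs += 1
    return total / npairs


def logrank_chi2_two_group(time, event, group) -> float:
    """Two-group log-rank chi-square from the observed-minus-expected sums."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e ** 2 / var) if var > 0 else 0.0
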
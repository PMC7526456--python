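"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: closed-form sphere
geometry, Monte-Carlo surface sampling with random directions, and a
brute-force search over rotation space.  They exist to cross-check the
production code, so they must stay simple even where slow.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def isolated_sphere_area(r: float, probe: float) -> float:
    return 4.0 * math.pi * (r + probe) ** 2


def two_sphere_areas(r1: float, r2: float, d: float, probe: float) -> tuple[float, float]:
    """Exact accessible areas of two intersecting expanded spheres.

    Each sphere of radius ``R_i = r_i + probe`` loses the spherical cap cut
    off by the other sphere: ``A_i = 4 pi R_i^2 - 2 pi R_i h_i`` with cap
    height ``h_i = R_i - x_i`` and ``x_i`` the distance from center i to the
    radical plane.
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1 ** 2, 4 * math.pi * R2 ** 2
    if d + min(R1, R2) <= max(R1, R2):  # one sphere swallowed
        if R1 < R2:
            return 0.0, 4 * math.pi * R2 ** 2
        return 4 * math.pi * R1 ** 2, 0.0
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    a1 = 4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * h1
    a2 = 4 * math.pi * R2 ** 2 - 2 * math.pi * R2 * h2
    return a1, a2


def mc_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
            n_samples: int = 20000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo per-atom SASA: random surface points on each expanded
    sphere, accessible if outside every other expanded sphere."""
    rng = np.random.default_rng(seed)
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    expanded = radii + probe
    n = len(coords)
    areas = np.empty(n)
    for i in range(n):
        v = rng.normal(size=(n_samples, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pts = coords[i] + expanded[i] * v
        free = np.ones(n_samples, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            free &= d2 >= expanded[j] ** 2
        areas[i] = free.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD of centered P onto centered Q over all proper rotations,
    by coarse Euler-angle grid search followed by local refinement."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    n = len(P)

    def rmsd_of(euler: np.ndarray) -> float:
        R = Rotation.from_euler("zyz", euler).as_matrix()
        return float(np.sqrt((((P @ R.T) - Q) ** 2).sum() / n))

    grid = np.linspace(-np.pi, np.pi, 13)
    half = np.linspace(0.0, np.pi, 7)
    best_val, best_e = np.inf, None
    for a in grid:
        for b in half:
            for c in grid:
                v = rmsd_of(np.array([a, b, c]))
                if v < best_val:
                    best_val, best_e = v, np.array([a, b, c])
    res = minimize(rmsd_of, best_e, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
    return float(min(best_val, res.fun))
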
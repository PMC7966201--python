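"""Independent oracles for cross-checking the closed-form registration path.

Nothing here calls holonav's Kabsch solver: the nonlinear oracle optimises
the six motion parameters directly with scipy.optimize.least_squares, and
the permutation oracle uses scipy's align_vectors (its own Kabsch) per
candidate correspondence.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


def lsq_rigid_oracle(src: np.ndarray, dst: np.ndarray, n_restarts: int = 10,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Six-parameter (rotation-vector + translation) nonlinear least squares.

    Multi-started to dodge local minima on SO(3).  Returns (R, t, fre).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    rng = np.random.default_rng(seed)

    def residuals(params):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return ((src @ R.T + params[3:]) - dst).ravel()

    best = None
    starts = [np.zeros(6)]
    for _ in range(n_restarts):
        rv = rng.normal(size=3)
        rv *= rng.uniform(0, np.pi) / max(np.linalg.norm(rv), 1e-12)
        t0 = dst.mean(axis=0) - src.mean(axis=0)
        starts.append(np.concatenate([rv, t0 + rng.normal(0, 10, 3)]))
    for x0 in starts:
        sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    t = best.x[3:]
    fre = float(np.sqrt(np.mean(np.sum((src @ R.T + t - dst) ** 2, axis=1))))
    return R, t, fre


def align_vectors_rigid(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form rigid fit via scipy's Kabsch (align_vectors)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - cd, src - cs)
    R = rot.as_matrix()
    return R, cd - R @ cs


def best_permutation_fre(src: np.ndarray, dst: np.ndarray) -> float:
    """Exhaustive-correspondence FRE: best over all bijections src→dst."""
    n = len(src)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        R, t = align_vectors_rigid(src, dst[list(perm)])
        fre = np.sqrt(np.mean(np.sum((src @ R.T + t - dst[list(perm)]) ** 2, axis=1)))
        best = min(best, float(fre))
    return best
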
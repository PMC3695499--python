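"""Independent oracles used by the test suite.

These deliberately avoid the package's superposition code path: the grid
minimizer searches rotation space directly (axis-angle grid with local
refinement), and the membership oracle recomputes sphere contents from raw
pairwise distances.
"""

from __future__ import annotations

import numpy as np


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def grid_min_rmsd(
    ref: np.ndarray,
    mov: np.ndarray,
    n_axes: int = 1200,
    coarse_step_deg: float = 2.0,
    final_step_deg: float = 0.05,
) -> float:
    """Minimum RMSD over proper rotations, by brute-force grid search.

    Exploits rmsd^2 = (E0 - 2 tr(R C)) / n with C the cross-covariance, so
    each candidate rotation costs O(1): for axis u and angle t,
    tr(R C) = cos t (tr C - u^T C u) + sin t (u . w) + u^T C u, where w is
    the axial vector of C.  A coarse axis/angle grid is followed by local
    refinement around the best few candidates down to ``final_step_deg``.
    Translations are handled exactly by centering.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    n = ref.shape[0]
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    cov = mov_c.T @ ref_c
    e0 = float((ref_c**2).sum() + (mov_c**2).sum())
    tr_cov = float(np.trace(cov))
    axial = np.array(
        [cov[2, 1] - cov[1, 2], cov[0, 2] - cov[2, 0], cov[1, 0] - cov[0, 1]]
    )

    def trace_grid(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
        a = np.einsum("ki,ij,kj->k", axes, cov, axes)
        b = axes @ axial
        return (
            np.cos(angles)[None, :] * (tr_cov - a[:, None])
            + np.sin(angles)[None, :] * b[:, None]
            + a[:, None]
        )

    axes = _fibonacci_sphere(n_axes)
    angles = np.deg2rad(np.arange(0.0, 360.0, coarse_step_deg))
    grid = trace_grid(axes, angles)
    flat = np.argsort(grid, axis=None)[-4:]  # refine the best few basins

    best_trace = -np.inf
    for idx in flat:
        ai, ti = np.unravel_index(idx, grid.shape)
        axis = axes[ai]
        angle = angles[ti]
        axis_window = np.deg2rad(8.0)
        angle_window = np.deg2rad(2.0 * coarse_step_deg)
        step = np.deg2rad(coarse_step_deg)
        while True:
            # local axis samples in a cap around the current best axis
            perp = np.zeros(3)
            perp[np.argmin(np.abs(axis))] = 1.0
            u = np.cross(axis, perp)
            u /= np.linalg.norm(u)
            v = np.cross(axis, u)
            offsets = np.linspace(-axis_window, axis_window, 9)
            local_axes = []
            for du in offsets:
                for dv in offsets:
                    cand = axis + du * u + dv * v
                    local_axes.append(cand / np.linalg.norm(cand))
            local_axes = np.asarray(local_axes)
            local_angles = angle + np.linspace(-angle_window, angle_window, 17)
            local = trace_grid(local_axes, local_angles)
            ai2, ti2 = np.unravel_index(np.argmax(local), local.shape)
            axis = local_axes[ai2]
            angle = float(local_angles[ti2])
            best_trace = max(best_trace, float(local[ai2, ti2]))
            if step <= np.deg2rad(final_step_deg):
                break
            axis_window *= 0.25
            angle_window *= 0.25
            step *= 0.25

    return float(np.sqrt(max(0.0, e0 - 2.0 * best_trace) / n))


def sphere_membership(
    coords: np.ndarray, center: np.ndarray, radius: float
) -> np.ndarray:
    """Boolean closed-ball membership from raw pairwise distances."""
    coords = np.asarray(coords, dtype=float)
    deltas = coords - np.asarray(center, dtype=float)
    return np.sqrt((deltas**2).sum(axis=1)) <= radius
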
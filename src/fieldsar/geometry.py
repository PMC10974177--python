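"""Rigid-body superposition utilities shared by the QSAR alignment and the
trajectory analyses.

The Kabsch algorithm finds the proper rotation (det = +1, never a reflection)
and translation minimizing the RMSD between two paired point sets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "apply_rigid", "rmsd"]


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays
        Paired coordinates in Å. ``n`` must be >= 3 and the points must not
        be collinear for the rotation to be well determined.
    weights : (n,) array, optional
        Per-point weights (e.g. masses). Uniform if omitted.

    Returns
    -------
    (R, t, rmsd_val)
        such that ``mobile @ R.T + t`` best fits ``reference``;
        ``det(R) == +1``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects matching (n, 3) coordinate arrays")
    n = P.shape[0]
    if n < 2:
        raise ValueError("kabsch needs at least 2 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()

    p_cen = w @ P
    q_cen = w @ Q
    Pc = P - p_cen
    Qc = Q - q_cen

    # With < 3 non-collinear points the optimal rotation is not unique
    # (free spin about the common axis), but the minimized RMSD still is;
    # the SVD below returns one RMSD-optimal proper rotation either way.
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_cen - R @ p_cen

    fitted = Pc @ R.T
    rmsd_val = float(np.sqrt(np.sum(w[:, None] * (fitted - Qc) ** 2)))
    return R, t, rmsd_val


def apply_rigid(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply the rigid transform ``x -> R x + t`` to an (n, 3) array."""
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (no superposition) RMSD between paired coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = np.sum((a - b) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt(np.sum(w * d2) / w.sum()))
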
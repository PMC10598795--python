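"""Rigid-body geometry helpers: Kabsch superposition and random transforms.

All coordinates are in angstroms, as (n, 3) float arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "apply_transform", "random_rotation", "rmsd", "angle_between"]


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping point set ``P`` onto ``Q``.

    Returns ``(R, t, rmsd)`` such that ``R @ p + t`` best approximates ``q``
    for corresponding rows, with ``R`` a proper rotation. Degenerate sizes
    (1 or 2 points) are handled: the rotation is then only determined up to
    the unresolved degrees of freedom, but the residual is still the true
    least-squares minimum.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {P.shape} and {Q.shape}")
    if len(P) == 0:
        raise ValueError("cannot superpose empty point sets")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    res = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, res


def apply_transform(R: np.ndarray, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Apply ``x -> R @ x + t`` to each row of ``X``."""
    return np.asarray(X, dtype=float) @ np.asarray(R, dtype=float).T + np.asarray(t, dtype=float)


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return float(np.sqrt(((P - Q) ** 2).sum() / len(P)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two vectors (0 for parallel)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length vector has no direction")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))
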
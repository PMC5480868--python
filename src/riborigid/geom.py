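"""Small geometry helpers: least-squares superposition and dihedrals."""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``mobile`` onto ``target``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the
    (weighted) RMSD to ``target``. Proper rotation only (reflections are
    removed), which is the standard SVD/quaternion result.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if weights is None:
        w = np.ones(len(mobile))
    else:
        w = np.asarray(weights, float)
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    tc = (w[:, None] * target).sum(axis=0)
    H = (w[:, None] * (mobile - mc)).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    R, t = kabsch(mobile, target, weights)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray,
         weights: np.ndarray | None = None) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Four-point torsion angle in degrees in [0, 360)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang % 360.0)
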
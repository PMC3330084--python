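"""Rigid-body superposition and internal-coordinate helpers.

All angles are returned in radians unless noted; coordinates are in Å.
"""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best matches
    ``reference`` in the least-squares sense, together with the post-fit RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"selection size mismatch: {mobile.shape[0]} vs {reference.shape[0]} points"
        )
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    P = mobile - mu_m
    Q = reference - mu_r
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    fitted = P @ R.T + mu_r
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ R.T + t


def rmsd_after_fit(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal rigid superposition."""
    return kabsch(mobile, reference)[2]


def pseudo_angles(coords: np.ndarray) -> np.ndarray:
    """Angle at each interior point of a polyline (e.g. consecutive CA triples).

    Returns an array of length ``n - 2`` with the angle i-1, i, i+1 for
    i = 1 .. n-2.
    """
    coords = np.asarray(coords, dtype=float)
    b1 = coords[:-2] - coords[1:-1]
    b2 = coords[2:] - coords[1:-1]
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    cosang = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def pseudo_dihedrals(coords: np.ndarray) -> np.ndarray:
    """Torsion angle for each consecutive quadruple of points, length ``n - 3``.

    Signed, in (-pi, pi], following the IUPAC convention.
    """
    coords = np.asarray(coords, dtype=float)
    b1 = coords[1:-2] - coords[:-3]
    b2 = coords[2:-1] - coords[1:-2]
    b3 = coords[3:] - coords[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    return np.arctan2(y, x)


def angle_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest absolute difference between two angle arrays (radians)."""
    d = np.abs(np.asarray(a) - np.asarray(b))
    return np.minimum(d, 2.0 * np.pi - d)


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )
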
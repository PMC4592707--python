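"""Elementary vector geometry: internal coordinates, atom placement, superposition.

All lengths are in Å and angles in degrees at the public surface; internal
trigonometry uses radians.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex ``b`` in degrees."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to ``c`` using internal coordinates (NeRF).

    ``length`` = |D-c|, ``angle`` = D-c-b in degrees, ``torsion`` = dihedral
    D-c-b-a in degrees.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -length * np.cos(ang),
        length * np.sin(ang) * np.cos(tor),
        length * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray,
                    weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation superposing centered ``mobile`` onto centered ``target``.

    Returns ``(R, t_mobile, t_target)`` where the superposed coordinates are
    ``(mobile - t_mobile) @ R.T + t_target``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if weights is None:
        cm = mobile.mean(axis=0)
        ct = target.mean(axis=0)
    else:
        w = np.asarray(weights, float)
        cm = (mobile * w[:, None]).sum(0) / w.sum()
        ct = (target * w[:, None]).sum(0) / w.sum()
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm, weights=weights)
    return rot.as_matrix(), cm, ct


def superpose(mobile: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``target`` (Kabsch)."""
    R, cm, ct = kabsch_rotation(mobile, target, weights)
    return (np.asarray(mobile, float) - cm) @ R.T + ct


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray,
                             weights: np.ndarray | None = None) -> float:
    """Minimum RMSD between two point sets over all rigid superpositions."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    moved = superpose(b, a, weights)
    d2 = np.sum((a - moved) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, float)
    return float(np.sqrt((w * d2).sum() / w.sum()))
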
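"""Small 3D linear-algebra helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(a))
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return a / n


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    a = unit(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]],
                  [a[2], 0, -a[0]],
                  [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def project_out(v, n) -> np.ndarray:
    """Component of ``v`` perpendicular to unit vector ``n``."""
    n = unit(n)
    v = np.asarray(v, dtype=float)
    return v - np.dot(v, n) * n


def signed_angle_about(u, v, axis) -> float:
    """Signed angle (degrees) from ``u`` to ``v`` measured about ``axis``,
    both projected onto the plane perpendicular to ``axis``."""
    a = unit(axis)
    up = unit(project_out(u, a))
    vp = unit(project_out(v, a))
    return float(np.degrees(np.arctan2(np.dot(np.cross(up, vp), a), np.dot(up, vp))))
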
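"""Plane mappings shared across the alignment stages.

A "mapping" in this package is any object with an ``apply(points) -> points``
method on (N, 2) arrays. :class:`Homography` is the projective case; the
thin-plate-spline case lives in :mod:`potkit.tps`.
"""

from __future__ import annotations

import numpy as np


class Homography:
    """A 3x3 projective transform acting on (x, y) points.

    The matrix is stored normalized to unit Frobenius norm with a positive
    bottom-right element (when nonzero), so two matrices describing the same
    transform compare equal.
    """

    def __init__(self, matrix: np.ndarray):
        H = np.asarray(matrix, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("homography must be a 3x3 matrix")
        if abs(np.linalg.det(H)) < 1e-12:
            raise ValueError("homography matrix is singular")
        H = H / np.linalg.norm(H)
        if H[2, 2] < 0 or (H[2, 2] == 0 and H.ravel()[np.argmax(np.abs(H))] < 0):
            H = -H
        self.matrix = H

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Homography":
        H = np.eye(3)
        H[0, 2], H[1, 2] = tx, ty
        return cls(H)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ones = np.ones((len(pts), 1))
        proj = np.hstack([pts, ones]) @ self.matrix.T
        return proj[:, :2] / proj[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """Return the mapping ``self o other`` (other applied first)."""
        return Homography(self.matrix @ other.matrix)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Homography({np.array_str(self.matrix, precision=4)})"


def bilinear_sample(field: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinearly sample a (H, W) or (H, W, C) field at float (x, y) points.

    Points are clamped to the valid interpolation domain.
    """
    field = np.asarray(field, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    H, W = field.shape[:2]
    x = np.clip(pts[:, 0], 0.0, W - 1.0)
    y = np.clip(pts[:, 1], 0.0, H - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, W - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, H - 2)
    fx = x - x0
    fy = y - y0
    if field.ndim == 2:
        f = field[..., None]
    else:
        f = field
    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy
    out = (
        f[y0, x0] * w00[:, None]
        + f[y0, x0 + 1] * w10[:, None]
        + f[y0 + 1, x0] * w01[:, None]
        + f[y0 + 1, x0 + 1] * w11[:, None]
    )
    return out[:, 0] if field.ndim == 2 else out
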
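"""Landmark-based perspective registration between two image frames.

Estimates the 3x3 projective transform H mapping source-frame pixel
coordinates (x, y) to destination-frame coordinates (x', y') from >= 4
landmark pairs, by normalized DLT followed by least-squares refinement of the
back-projection error

    sum_i (x'_i - (h11 x_i + h12 y_i + h13)/(h31 x_i + h32 y_i + h33))^2
        + (y'_i - (h21 x_i + h22 y_i + h23)/(h31 x_i + h32 y_i + h33))^2

Coordinates are 0-based with x = column index, y = row index and pixel
centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LandmarkSet",
    "Homography",
    "DegenerateLandmarksError",
    "estimate_homography",
    "backprojection_error",
    "project_points",
    "warp_mask",
]


class DegenerateLandmarksError(ValueError):
    """Landmark configuration does not determine a unique homography."""


@dataclass
class LandmarkSet:
    """Paired pixel coordinates: ``src[i] -> dst[i]``, both ``(N, 2)`` as (x, y)."""

    src: np.ndarray
    dst: np.ndarray
    source_frame: str = "colposcope"
    destination_frame: str = "hsi"

    def __post_init__(self) -> None:
        self.src = np.atleast_2d(np.asarray(self.src, dtype=np.float64))
        self.dst = np.atleast_2d(np.asarray(self.dst, dtype=np.float64))
        if self.src.shape != self.dst.shape or self.src.shape[1] != 2:
            raise ValueError("src and dst must both be (N, 2) arrays")
        if not (np.all(np.isfinite(self.src)) and np.all(np.isfinite(self.dst))):
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.src.shape[0]


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform, normalized to h33 = 1 when possible."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        if h.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        norm = np.linalg.norm(h)
        # determinant of the unit-norm matrix: scale-invariant singularity test
        if norm == 0 or abs(np.linalg.det(h / norm)) < 1e-12:
            raise ValueError("homography is singular")
        object.__setattr__(self, "h", _normalize(h))

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    @classmethod
    def translation(cls, tx: float, ty: float) -> "Homography":
        h = np.eye(3)
        h[0, 2] = tx
        h[1, 2] = ty
        return cls(h)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.h))

    def __matmul__(self, other: "Homography") -> "Homography":
        return Homography(self.h @ other.h)


def _normalize(h: np.ndarray) -> np.ndarray:
    # h33 = 1 convention; fall back to unit Frobenius norm for affinities at
    # infinity (h33 ~ 0 relative to the rest of the matrix)
    if abs(h[2, 2]) > 1e-8 * np.abs(h).max():
        return h / h[2, 2]
    return h / np.linalg.norm(h)


def _collinear(p: np.ndarray, q: np.ndarray, r: np.ndarray, tol: float = 1e-9) -> bool:
    area2 = abs((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))
    scale = max(np.abs(np.vstack([p, q, r])).max(), 1.0)
    return area2 <= tol * scale * scale


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform bringing points to centroid 0, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    t = np.array(
        [[s, 0.0, -s * centroid[0]], [0.0, s, -s * centroid[1]], [0.0, 0.0, 1.0]]
    )
    return t


def project_points(H: Homography, points: np.ndarray) -> np.ndarray:
    """Homogeneous multiply then perspective divide; ``points`` is (N, 2) (x, y)."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    ones = np.ones((pts.shape[0], 1))
    ph = np.hstack([pts, ones]) @ H.h.T
    w = ph[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point mapped to infinity (w = 0)")
    out = ph[:, :2] / w[:, None]
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def backprojection_error(H: Homography, landmarks: LandmarkSet) -> float:
    """Total squared residual between projected sources and destinations."""
    proj = project_points(H, landmarks.src)
    return float(((proj - landmarks.dst) ** 2).sum())


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    n = src.shape[0]
    a = np.zeros((2 * n, 9))
    x, y = src[:, 0], src[:, 1]
    xp, yp = dst[:, 0], dst[:, 1]
    a[0::2, 0] = x
    a[0::2, 1] = y
    a[0::2, 2] = 1.0
    a[0::2, 6] = -xp * x
    a[0::2, 7] = -xp * y
    a[0::2, 8] = -xp
    a[1::2, 3] = x
    a[1::2, 4] = y
    a[1::2, 5] = 1.0
    a[1::2, 6] = -yp * x
    a[1::2, 7] = -yp * y
    a[1::2, 8] = -yp
    _, s, vt = np.linalg.svd(a)
    # a unique solution requires a one-dimensional null space
    if s[-2] <= 1e-9 * s[0]:
        raise DegenerateLandmarksError(
            "landmark configuration is degenerate (homography not unique)"
        )
    return vt[-1].reshape(3, 3)


def estimate_homography(landmarks: LandmarkSet) -> Homography:
    """Estimate H from >= 4 landmark pairs (normalized DLT + refinement).

    Raises :class:`ValueError` for fewer than 4 pairs and
    :class:`DegenerateLandmarksError` for collinear/degenerate configurations.
    """
    n = len(landmarks)
    if n < 4:
        raise ValueError(f"homography estimation requires >= 4 landmark pairs, got {n}")
    src, dst = landmarks.src, landmarks.dst
    if n == 4:
        for pts, name in ((src, "source"), (dst, "destination")):
            for skip in range(4):
                tri = [pts[i] for i in range(4) if i != skip]
                if _collinear(*tri):
                    raise DegenerateLandmarksError(
                        f"three {name} landmarks are collinear; "
                        "homography is not uniquely determined"
                    )
    ts = _hartley_normalization(src)
    td = _hartley_normalization(dst)
    src_n = (np.hstack([src, np.ones((n, 1))]) @ ts.T)[:, :2]
    dst_n = (np.hstack([dst, np.ones((n, 1))]) @ td.T)[:, :2]
    h_n = _dlt(src_n, dst_n)
    h0 = _normalize(np.linalg.inv(td) @ h_n @ ts)

    if abs(h0[2, 2]) > 1e-8:
        # refine the 8 free parameters (h33 pinned at 1) against the printed
        # objective; DLT minimizes an algebraic proxy, this is the geometric one
        def residuals(p: np.ndarray) -> np.ndarray:
            h = np.append(p, 1.0).reshape(3, 3)
            ph = np.hstack([src, np.ones((n, 1))]) @ h.T
            w = ph[:, 2]
            w = np.where(np.abs(w) < 1e-12, 1e-12, w)
            return ((ph[:, :2] / w[:, None]) - dst).ravel()

        sol = least_squares(residuals, h0.ravel()[:8], method="lm", xtol=1e-15, ftol=1e-15)
        h = np.append(sol.x, 1.0).reshape(3, 3)
    else:
        h = h0
    return Homography(h)


def warp_mask(
    H: Homography, mask: np.ndarray, destination_shape: tuple[int, int]
) -> np.ndarray:
    """Warp a binary mask from the source frame into the destination frame.

    Each destination pixel center is mapped through H^-1; the pixel is set iff
    the nearest source pixel is set.  Out-of-bounds maps to 0.  Nearest
    neighbor keeps the output strictly binary.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    dh, dw = destination_shape
    if dh <= 0 or dw <= 0:
        raise ValueError("destination shape must be positive")
    hinv = H.inverse().h
    xs, ys = np.meshgrid(np.arange(dw, dtype=np.float64), np.arange(dh, dtype=np.float64))
    ph = np.stack([xs, ys, np.ones_like(xs)], axis=-1) @ hinv.T
    w = ph[..., 2]
    valid = np.abs(w) > 1e-12
    w_safe = np.where(valid, w, 1.0)
    sx = np.rint(ph[..., 0] / w_safe).astype(np.int64)
    sy = np.rint(ph[..., 1] / w_safe).astype(np.int64)
    inb = valid & (sx >= 0) & (sx < mask.shape[1]) & (sy >= 0) & (sy < mask.shape[0])
    out = np.zeros((dh, dw), dtype=bool)
    out[inb] = mask[sy[inb], sx[inb]]
    return out
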
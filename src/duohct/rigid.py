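"""Rigid (translation + rotation about image centre) resampling helpers.

Convention: a rigid offset ``(dx_px, dy_px, theta_deg)`` first rotates the
image content by ``theta_deg`` counter-clockwise about the image centre,
then translates it by ``dx_px`` columns and ``dy_px`` rows.  The pixel grid
is row-major, origin top-left, 0-based; transform parameters are expressed
in (x, y) = (column, row) axes.  Out-of-frame samples are filled with 0.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import ProjectiveTransform, warp

__all__ = ["rigid_matrix", "warp_rigid", "invert_params"]


def rigid_matrix(dx_px: float, dy_px: float, theta_deg: float,
                 shape: tuple[int, int]) -> np.ndarray:
    """3x3 homogeneous forward matrix in (x, y) coordinates.

    Maps a source coordinate to where its content lands: rotation about the
    image centre followed by the (dx, dy) translation.
    """
    theta = np.deg2rad(theta_deg)
    cx = (shape[1] - 1) / 2.0
    cy = (shape[0] - 1) / 2.0
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t_in = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    t_out = np.array([[1, 0, cx + dx_px], [0, 1, cy + dy_px], [0, 0, 1]], dtype=float)
    return t_out @ rot @ t_in


def invert_params(dx_px: float, dy_px: float, theta_deg: float,
                  shape: tuple[int, int]) -> np.ndarray:
    """Forward matrix of the inverse rigid offset (undoes the offset)."""
    return np.linalg.inv(rigid_matrix(dx_px, dy_px, theta_deg, shape))


def _integer_shift(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape
    src_r = slice(max(0, -dy), min(h, h - dy))
    dst_r = slice(max(0, dy), min(h, h + dy))
    src_c = slice(max(0, -dx), min(w, w - dx))
    dst_c = slice(max(0, dx), min(w, w + dx))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def warp_rigid(img: np.ndarray, dx_px: float, dy_px: float, theta_deg: float,
               order: int = 3, matrix: np.ndarray | None = None) -> np.ndarray:
    """Resample ``img`` under the forward rigid offset.

    The zero transform returns the input values bit-identically; a pure
    integer translation is applied exactly (no interpolation).  Otherwise a
    spline interpolation of the given order is used with zero fill.
    """
    if matrix is None:
        if theta_deg == 0.0 and dx_px == round(dx_px) and dy_px == round(dy_px):
            if dx_px == 0.0 and dy_px == 0.0:
                return img.copy()
            return _integer_shift(img, int(round(dx_px)), int(round(dy_px)))
        matrix = rigid_matrix(dx_px, dy_px, theta_deg, img.shape)
    # warp() expects the output->input map; pass the inverse of the forward map.
    tform = ProjectiveTransform(matrix=np.linalg.inv(matrix))
    return warp(img.astype(float), tform, order=order, mode="constant",
                cval=0.0, preserve_range=True)
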
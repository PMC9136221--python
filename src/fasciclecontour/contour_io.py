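"""Mask reading, boundary tracing and contour canonicalization.

Fascicle cross-sections arrive as binary segmentation masks (one
foreground region per mask).  This module extracts the ordered closed
boundary of the region and puts it into the canonical frame used by the
contour models: centroid at the origin, mathematical y-up axes, counter-
clockwise orientation, starting point on the positive real axis.

Coordinate convention: a pixel at image position (row, col) maps to the
point (x, y) = (col, -row).  Flipping the row axis makes "counter-
clockwise" in the complex plane match the usual orientation language;
pixel centers sit at integer coordinates (0-based).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "read_mask",
    "write_contour",
    "read_contour",
    "trace_boundary",
    "center_on_centroid",
    "canonicalize_start",
    "canonicalize",
    "signed_area",
    "mask_centroid",
    "split_components",
]

# Moore neighborhood in clockwise image order starting from the west
# neighbor: (drow, dcol).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def read_mask(path) -> np.ndarray:
    """Read a PNG/TIFF image as a binary mask (any nonzero pixel -> 1)."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 3 and arr.shape[2] in (2, 4):  # drop alpha
        arr = arr[..., :-1]
    if arr.ndim == 3:  # collapse color planes
        arr = arr.max(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF (foreground = 255)."""
    mask = np.asarray(mask)
    Image.fromarray((mask > 0).astype(np.uint8) * 255).save(path)


def write_contour(contour: np.ndarray, path) -> None:
    """Write contour points to CSV with an ``x,y`` header."""
    contour = np.asarray(contour, dtype=float)
    pd.DataFrame(contour, columns=["x", "y"]).to_csv(path, index=False)


def read_contour(path) -> np.ndarray:
    """Read an ordered contour from a CSV file with columns x, y."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty contour file: {path}")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV must have columns x,y; missing {sorted(missing)}")
    return df[["x", "y"]].to_numpy(dtype=float)


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    bad = ~np.isin(mask, (0, 1))
    if bad.any():
        raise ValueError("mask values must be exactly 0 or 1")
    return mask


def split_components(mask: np.ndarray) -> list[np.ndarray]:
    """Split a multi-region mask into one single-region mask per
    8-connected foreground component, ordered by label."""
    mask = _validate_mask(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    return [(labels == i).astype(np.uint8) for i in range(1, n + 1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the ordered pixel boundary of the single foreground region.

    Moore-neighbor tracing on the 8-connected component, with Jacob's
    stopping criterion (terminate on re-entering the start pixel from the
    starting direction).  Returns an (N, 2) array of (x, y) points in the
    math frame (x = col, y = -row), one full loop, without repeating the
    closing point.

    Raises
    ------
    ValueError
        If the mask is empty or contains more than one 8-connected
        foreground component (split multi-region masks first, e.g. with
        :func:`split_components`).
    """
    mask = _validate_mask(mask)
    if not mask.any():
        raise ValueError("no foreground pixels in mask")
    _, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        raise ValueError(
            f"mask has {n} foreground components; label and split them first "
            "(split_components)"
        )

    padded = np.pad(mask, 1)
    rows, cols = np.nonzero(padded)
    # uppermost-leftmost foreground pixel; its west neighbor is background
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))
    b0 = (start[0], start[1] - 1)  # initial backtrack: west neighbor

    dir_index = {d: i for i, d in enumerate(_MOORE)}
    boundary: list[tuple[int, int]] = [start]
    p, b = start, b0
    seen = {(p, b)}
    while True:
        d0 = dir_index[(b[0] - p[0], b[1] - p[1])]
        for step in range(1, 9):
            d = (d0 + step) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if padded[q]:
                # backtrack for the next pixel: last background scanned
                dprev = (d - 1) % 8
                b = (p[0] + _MOORE[dprev][0], p[1] + _MOORE[dprev][1])
                p = q
                break
        else:  # isolated pixel: no foreground neighbor
            break
        # the walk is a function of (pixel, backtrack); a repeated state
        # closes the loop (Jacob's stopping criterion when it is the
        # initial state, which it is for valid single components)
        if (p, b) in seen:
            break
        seen.add((p, b))
        boundary.append(p)

    pts = np.array(boundary, dtype=float) - 1.0  # undo padding offset
    # image (row, col) -> math (x, y)
    return np.column_stack([pts[:, 1], -pts[:, 0]])


def signed_area(contour: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise in the math frame."""
    c = np.asarray(contour, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Foreground-pixel centroid of a mask, in the math frame (x, y)."""
    mask = _validate_mask(mask)
    if not mask.any():
        raise ValueError("no foreground pixels in mask")
    rows, cols = np.nonzero(mask)
    return float(cols.mean()), float(-rows.mean())


def center_on_centroid(contour: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Translate a traced contour so the region centroid is the origin.

    The centroid is the mean of the foreground *pixel* coordinates of the
    mask the contour was traced from (robust to uneven boundary sampling),
    not the mean of the boundary points.
    """
    contour = np.asarray(contour, dtype=float)
    mask = _validate_mask(mask)
    h, w = mask.shape
    x, y = contour[:, 0], contour[:, 1]
    if (x < -0.5).any() or (x > w - 0.5).any() or (y > 0.5).any() or (y < -(h - 0.5)).any():
        raise ValueError("contour points fall outside the mask bounds; mismatched inputs?")
    cx, cy = mask_centroid(mask)
    return contour - np.array([cx, cy])


def canonicalize_start(contour: np.ndarray) -> np.ndarray:
    """Force counterclockwise orientation and a positive-real-axis start.

    The contour is traversed counterclockwise (reversed if its signed
    area is negative) and rotated so the first point is the one closest
    in angle to the positive x-axis (minimal ``|atan2(y, x)|``); ties go
    to the smaller index in the oriented sequence.  Idempotent.
    """
    contour = np.asarray(contour, dtype=float)
    if len(contour) < 3:
        raise ValueError("contour must have at least 3 points")
    if signed_area(contour) < 0:
        contour = contour[::-1]
    ang = np.abs(np.arctan2(contour[:, 1], contour[:, 0]))
    start = int(np.argmin(ang))  # argmin takes the first (smallest index) on ties
    return np.roll(contour, -start, axis=0)


def canonicalize(mask: np.ndarray) -> np.ndarray:
    """Trace, center and canonicalize in one step: mask -> canonical contour."""
    contour = trace_boundary(mask)
    if len(contour) < 3:
        raise ValueError("degenerate region: fewer than 3 boundary pixels")
    contour = center_on_centroid(contour, mask)
    return canonicalize_start(contour)
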
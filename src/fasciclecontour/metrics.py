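"""Model-accuracy metrics: Dice overlap, directed Hausdorff distance and
the relative Hausdorff error.

Dice (in percent) compares the pixel regions enclosed by the original
and the reconstructed contour:

    Dice = 2 |S_A & S_B| / (|S_A| + |S_B|) * 100

The boundary error of a reconstructed point b_x is its distance to the
nearest original point, e_x = min_y ||b_x - a_y||; the directed Hausdorff
distance H = max_x e_x is taken from the reconstruction onto the original
(not symmetrized).  Because the same H means different things on small
and large fascicles, it is normalized by the original contour's point
count N (a proxy for its perimeter in pixel-sampled contours):

    H_E = H / N * 100    (percent)

The working acceptance thresholds for a contour model are Dice >= 95%
and H_E <= 5%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bspline_model import BSplineModel, sample_curve
from .fourier_efd import FourierModel, efd_reconstruct

__all__ = [
    "MetricsReport",
    "rasterize",
    "dice",
    "directed_hausdorff",
    "relative_hausdorff",
    "evaluate",
    "DICE_MIN",
    "HE_MAX",
]

DICE_MIN = 95.0  # percent
HE_MAX = 5.0  # percent


@dataclass(frozen=True)
class MetricsReport:
    dice: float  # percent
    hausdorff: float  # pixels
    h_e: float  # percent
    n_original: int
    area_original: int  # |S_A|, pixels
    area_model: int  # |S_B|, pixels

    def meets(self, dice_min: float = DICE_MIN, he_max: float = HE_MAX) -> bool:
        return self.dice >= dice_min and self.h_e <= he_max


def rasterize(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed polygon to a binary mask by even-odd filling.

    The contour must be in image pixel coordinates (x = col, y = row,
    both >= -0.5 and within ``shape``); a pixel is foreground when its
    center has an odd crossing number.  Deterministic scanline
    implementation; self-intersecting polygons fill by the even-odd rule.
    """
    c = np.asarray(contour, dtype=float)
    h, w = shape
    if (c[:, 0] < -0.5).any() or (c[:, 0] > w - 0.5).any() \
            or (c[:, 1] < -0.5).any() or (c[:, 1] > h - 0.5).any():
        raise ValueError("contour exceeds the target grid")
    x1, y1 = c[:, 0], c[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    parity = np.zeros((h, w + 1), dtype=np.int64)
    for xa, ya, xb, yb in zip(x1, y1, x2, y2):
        if ya == yb:
            continue  # horizontal edges never cross a scanline half-open
        if ya > yb:
            xa, xb, ya, yb = xb, xa, yb, ya
        r0 = int(np.ceil(ya))  # scanlines with ya <= r < yb (half-open)
        r1 = int(np.ceil(yb))
        rows = np.arange(max(r0, 0), min(r1, h))
        if rows.size == 0:
            continue
        xi = xa + (rows - ya) * (xb - xa) / (yb - ya)
        # half-open in x as well: a center exactly on a crossing counts as
        # right of a left edge (inside) and left of a right edge (outside),
        # so boundary ties are counted once and the fill is unbiased
        cols = np.clip(np.ceil(xi).astype(int), 0, w)
        parity[rows, cols] += 1
    mask = (np.cumsum(parity, axis=1)[:, :w] % 2).astype(np.uint8)
    return mask


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two same-shape binary masks, in percent."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must share grid dimensions")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("both masks are empty")
    return 200.0 * float(np.logical_and(a, b).sum()) / float(denom)


def directed_hausdorff(recon: np.ndarray, original: np.ndarray,
                       symmetric: bool = False) -> tuple[float, np.ndarray]:
    """Directed Hausdorff distance from the reconstructed point set onto
    the original, plus the per-point boundary errors e_x.

    ``symmetric=True`` returns the max of both directions instead; the
    evaluation index itself is always the directed form, so this is never
    the default.
    """
    b = np.asarray(recon, dtype=float)
    a = np.asarray(original, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    e, _ = cKDTree(a).query(b)
    h = float(e.max())
    if symmetric:
        rev, _ = cKDTree(b).query(a)
        h = max(h, float(rev.max()))
    return h, e


def relative_hausdorff(hausdorff: float, n_original: int) -> float:
    """Relative Hausdorff error H_E = H / N * 100 (percent)."""
    if n_original <= 0:
        raise ValueError("original point count must be positive")
    return hausdorff / n_original * 100.0


def _model_points(model, n_points: int) -> np.ndarray:
    if isinstance(model, FourierModel):
        return efd_reconstruct(model, n_points)
    if isinstance(model, BSplineModel):
        return sample_curve(model, n_points)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def evaluate(contour: np.ndarray, model, mask: np.ndarray | None = None,
             n_recon: int | None = None, pad: int = 4) -> MetricsReport:
    """Full metric report for a fitted model against its source contour.

    The model curve is sampled densely (default 10x the contour's point
    count), both curves are rasterized on a common grid, and Dice, the
    directed Hausdorff distance (model onto original) and H_E are
    computed.  All three are translation invariant, so by default the
    grid is built internally around the contour; pass ``mask`` to use an
    existing image grid instead (the contour must then be in that mask's
    math frame, x = col, y = -row).
    """
    c = np.asarray(contour, dtype=float)
    n = len(c)
    recon = _model_points(model, n_recon or max(10 * n, 720))
    h, _ = directed_hausdorff(recon, c)

    if mask is not None:
        grid = np.asarray(mask)
        to_pix = lambda p: np.column_stack([p[:, 0], -p[:, 1]])  # noqa: E731
        mask_a = grid.astype(np.uint8)
        mask_b = rasterize(to_pix(recon), grid.shape)
    else:
        allpts = np.vstack([c, recon])
        x0, y0 = allpts.min(axis=0) - pad
        x1, y1 = allpts.max(axis=0) + pad
        shape = (int(np.ceil(y1 - y0)) + 1, int(np.ceil(x1 - x0)) + 1)
        shift = lambda p: np.column_stack([p[:, 0] - x0, p[:, 1] - y0])  # noqa: E731
        mask_a = rasterize(shift(c), shape)
        mask_b = rasterize(shift(recon), shape)

    return MetricsReport(
        dice=dice(mask_a, mask_b),
        hausdorff=h,
        h_e=relative_hausdorff(h, n),
        n_original=n,
        area_original=int(mask_a.sum()),
        area_model=int(mask_b.sum()),
    )
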
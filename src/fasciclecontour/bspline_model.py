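"""Quasi-uniform cubic B-spline model of a closed contour.

The comparison model: m control points are sampled from the contour at
equal intervals, the control polygon is closed by appending wrap control
points, and the curve is

    c(u) = sum_i P_i N_{i,3}(u),   u in [0, 1]

with the basis N_{i,k} from the Cox-de Boor recursion over a uniform
(repetition degree 1) knot vector.  With degree-many wrap points the
closed curve is C^2 everywhere, including the seam.

Unlike the Fourier model the control points are raw contour samples, so
the parameterization depends on the contour's point count and carries no
shape semantics of its own; with m = 21 control points the model has
2 * 21 = 42 adjustable coordinates before closure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BSplineModel", "basis", "fit_closed_bspline", "eval_curve", "sample_curve"]

DEGREE = 3


def basis(i: int, k: int, u: float, knots: np.ndarray) -> float:
    """Cox-de Boor B-spline basis N_{i,k}(u) with 0/0 terms taken as 0.

    Degree 0 is the half-open indicator of the knot span [u_i, u_{i+1});
    higher degrees blend the two children linearly.
    """
    knots = np.asarray(knots, dtype=float)
    if not (knots[0] <= u < knots[-1]):
        raise ValueError(f"parameter u={u} outside knot range [{knots[0]}, {knots[-1]})")
    if i < 0 or i + k + 1 >= len(knots):
        raise IndexError("basis index out of range for the knot vector")
    if k == 0:
        return 1.0 if knots[i] <= u < knots[i + 1] else 0.0
    left_den = knots[i + k] - knots[i]
    right_den = knots[i + k + 1] - knots[i + 1]
    left = 0.0 if left_den == 0 else (u - knots[i]) / left_den * basis(i, k - 1, u, knots)
    right = 0.0 if right_den == 0 else (knots[i + k + 1] - u) / right_den * basis(i + 1, k - 1, u, knots)
    return left + right


@dataclass(frozen=True)
class BSplineModel:
    """Closed quasi-uniform cubic B-spline curve."""

    control_points: np.ndarray = field(repr=False)  # (M, 2), wrap points included
    degree: int = DEGREE
    knots: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 2 or len(cp) < self.degree + 1:
            raise ValueError("need at least degree+1 2-D control points")
        object.__setattr__(self, "control_points", cp)
        if self.knots is None:
            object.__setattr__(self, "knots", _uniform_knots(len(cp), self.degree))
        else:
            kn = np.asarray(self.knots, dtype=float)
            if np.any(np.diff(kn) < 0):
                raise ValueError("knot vector must be non-decreasing")
            object.__setattr__(self, "knots", kn)

    @property
    def domain(self) -> tuple[float, float]:
        """Valid parameter span [u_k, u_M] of the unclamped curve."""
        return float(self.knots[self.degree]), float(self.knots[len(self.control_points)])

    def to_json(self, path=None) -> str:
        obj = {"degree": self.degree,
               "control_points": self.control_points.tolist(),
               "knots": self.knots.tolist()}
        s = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "BSplineModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(control_points=np.asarray(obj["control_points"], dtype=float),
                   degree=int(obj["degree"]),
                   knots=np.asarray(obj["knots"], dtype=float))


def _uniform_knots(n_control: int, degree: int) -> np.ndarray:
    """Uniform knots placing the valid span on [0, 1]: u_j = (j - degree) / n_seg
    with n_seg = n_control - degree segments, all interior knots simple (r = 1)."""
    n_seg = n_control - degree
    return (np.arange(n_control + degree + 1) - degree) / n_seg


def fit_closed_bspline(contour: np.ndarray, n_control: int = 21,
                       by_arc_length: bool = False) -> BSplineModel:
    """Build the closed cubic model from equal-interval contour samples.

    ``n_control`` contour points are taken at equal index intervals
    (indices round(j N / m)); with ``by_arc_length`` the samples are
    instead equally spaced along the polygonal perimeter.  The control
    polygon is closed by re-appending the first ``degree`` samples.
    """
    c = np.asarray(contour, dtype=float)
    n = len(c)
    if n_control < 4:
        raise ValueError("need at least 4 control points for a cubic")
    if n_control > n:
        raise ValueError(f"cannot sample {n_control} control points from {n} contour points")
    if by_arc_length:
        seg = np.hypot(*(np.roll(c, -1, axis=0) - c).T)
        cum = np.concatenate([[0.0], np.cumsum(seg)])  # cum[-1] = perimeter
        targets = np.arange(n_control) / n_control * cum[-1]
        idx = np.clip(np.searchsorted(cum, targets), 0, n - 1)
    else:
        idx = np.round(np.arange(n_control) * n / n_control).astype(int) % n
    samples = c[idx]
    cp = np.vstack([samples, samples[:DEGREE]])  # periodic wrap
    return BSplineModel(control_points=cp)


def eval_curve(model: BSplineModel, u) -> np.ndarray:
    """Evaluate the curve at parameter(s) u in [0, 1].

    Vectorized de Boor-style evaluation through the basis functions of
    the at most degree+1 active control points; u = 1 is evaluated as the
    left limit (which coincides with u = 0 on the closed curve).
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    lo, hi = model.domain
    if np.any(u_arr < lo) or np.any(u_arr > hi):
        raise ValueError(f"parameter outside [{lo}, {hi}]")
    knots, k = model.knots, model.degree
    pts = np.empty((len(u_arr), 2))
    eps = 1e-12
    for j, uj in enumerate(u_arr):
        uq = min(uj, hi - eps)  # left limit at the right end
        span = int(np.searchsorted(knots, uq, side="right") - 1)
        acc = np.zeros(2)
        for i in range(span - k, span + 1):
            w = basis(i, k, uq, knots)
            if w:
                acc += w * model.control_points[i]
        pts[j] = acc
    return pts[0] if np.isscalar(u) or np.ndim(u) == 0 else pts


def sample_curve(model: BSplineModel, n_points: int) -> np.ndarray:
    """Sample the closed curve at n_points uniform parameters in [0, 1)."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    return eval_curve(model, np.arange(n_points) / n_points)
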
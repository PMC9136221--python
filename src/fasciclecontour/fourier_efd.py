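"""Elliptic Fourier contour model.

A closed contour is mapped to the complex plane, z(t) = x(t) + i y(t),
with t the cumulative chord (arc) length of the point sequence.  Because
z is periodic with period T (the perimeter), x and y expand in a Fourier
series; truncating at order K gives the shape model

    x(t) = a0 + sum_k [ a_k cos(2 pi k t / T) + b_k sin(2 pi k t / T) ]
    y(t) = c0 + sum_k [ c_k cos(2 pi k t / T) + d_k sin(2 pi k t / T) ]

The coefficients are computed in closed form from the piecewise-linear
contour (the classical elliptic-Fourier-descriptor formulas): for each
harmonic k,

    a_k = T / (2 k^2 pi^2) * sum_p (dx_p / dt_p)
          * (cos(2 pi k t_p / T) - cos(2 pi k t_{p-1} / T))

and likewise b_k with sines, c_k/d_k with dy.  The constant terms a0, c0
are the parametric means of x(t), y(t) — the centroid of the curve — via
the standard accumulation with the xi/delta correction terms.

Order k = 1 is the fundamental (an ellipse); k >= 2 are harmonics that
add detail.  An order-K model has 4K shape parameters, plus a0 and c0
which only place the centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EFDIntermediates",
    "FourierModel",
    "arc_length_params",
    "efd_fit",
    "efd_reconstruct",
    "param_count",
]


@dataclass(frozen=True)
class EFDIntermediates:
    """Per-step quantities of the arc-length parameterization.

    Attributes
    ----------
    dx, dy : increments between consecutive points, with the wrap step
        from the last point back to the first (length N).
    dt : chord lengths sqrt(dx^2 + dy^2), all > 0.
    t : cumulative parameter, t[0] = 0 ... t[N] = T (length N + 1).
    T : total perimeter of the polygonal contour.
    xi, delta : accumulation terms entering the constant coefficients;
        xi[0] = delta[0] = 0.
    """

    dx: np.ndarray
    dy: np.ndarray
    dt: np.ndarray
    t: np.ndarray
    T: float
    xi: np.ndarray
    delta: np.ndarray


@dataclass(frozen=True)
class FourierModel:
    """Truncated elliptic Fourier model of a closed contour."""

    order: int
    a0: float
    c0: float
    coeffs: np.ndarray = field(repr=False)  # (order, 4): a_k, b_k, c_k, d_k

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if self.order < 1:
            raise ValueError("model order must be >= 1")
        if coeffs.shape != (self.order, 4):
            raise ValueError(f"coefficient table must be ({self.order}, 4), got {coeffs.shape}")
        object.__setattr__(self, "coeffs", coeffs)

    def param_vector(self, include_constants: bool = True) -> np.ndarray:
        """Parameters in the order a0, a1..aK, b1..bK, c0, c1..cK, d1..dK
        (constants dropped when ``include_constants`` is false)."""
        a, b, c, d = (self.coeffs[:, j] for j in range(4))
        if include_constants:
            return np.concatenate([[self.a0], a, b, [self.c0], c, d])
        return np.concatenate([a, b, c, d])

    def to_json(self, path=None) -> str:
        obj = {
            "order": self.order,
            "a0": self.a0,
            "c0": self.c0,
            "coeffs": self.coeffs.tolist(),
        }
        s = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "FourierModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(order=int(obj["order"]), a0=float(obj["a0"]), c0=float(obj["c0"]),
                   coeffs=np.asarray(obj["coeffs"], dtype=float))


def arc_length_params(contour: np.ndarray) -> EFDIntermediates:
    """Chord-length parameterization of a closed contour.

    Increments include the closing wrap (last point back to the first).
    Raises on consecutive duplicate points, naming the offending index.
    """
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or len(c) < 3:
        raise ValueError("contour must be an (N>=3, 2) point array")
    diff = np.roll(c, -1, axis=0) - c
    dx, dy = diff[:, 0], diff[:, 1]
    dt = np.hypot(dx, dy)
    zero = np.nonzero(dt == 0)[0]
    if zero.size:
        raise ValueError(f"consecutive duplicate contour points at index {int(zero[0])}")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = float(t[-1])
    # xi_p = sum_{j<p} dx_j - (dx_p / dt_p) sum_{j<p} dt_j   (xi_1 = 0)
    cum_dx = np.concatenate([[0.0], np.cumsum(dx)[:-1]])
    cum_dy = np.concatenate([[0.0], np.cumsum(dy)[:-1]])
    cum_dt = t[:-1]
    xi = cum_dx - dx / dt * cum_dt
    delta = cum_dy - dy / dt * cum_dt
    return EFDIntermediates(dx=dx, dy=dy, dt=dt, t=t, T=T, xi=xi, delta=delta)


def efd_fit(contour: np.ndarray, order: int) -> FourierModel:
    """Fit an order-K elliptic Fourier model to a closed contour.

    Deterministic closed-form projection; no optimization involved.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    c = np.asarray(contour, dtype=float)
    p = arc_length_params(c)
    T, t = p.T, p.t
    k = np.arange(1, order + 1)[:, None]  # (K, 1)
    phi = 2.0 * np.pi * t / T  # (N+1,)
    cos, sin = np.cos(k * phi), np.sin(k * phi)  # (K, N+1)
    dcos = cos[:, 1:] - cos[:, :-1]
    dsin = sin[:, 1:] - sin[:, :-1]
    pref = T / (2.0 * k.ravel() ** 2 * np.pi**2)  # (K,)
    sx, sy = p.dx / p.dt, p.dy / p.dt
    a = pref * (dcos @ sx)
    b = pref * (dsin @ sx)
    cc = pref * (dcos @ sy)
    d = pref * (dsin @ sy)

    # constant terms: parametric mean of x(t), y(t) over one period
    dt2 = t[1:] ** 2 - t[:-1] ** 2
    dtt = t[1:] - t[:-1]
    a0 = float(np.sum(p.dx / (2.0 * p.dt) * dt2 + p.xi * dtt) / T + c[0, 0])
    c0 = float(np.sum(p.dy / (2.0 * p.dt) * dt2 + p.delta * dtt) / T + c[0, 1])
    return FourierModel(order=order, a0=a0, c0=c0,
                        coeffs=np.column_stack([a, b, cc, d]))


def efd_reconstruct(model: FourierModel, n_points: int = 400) -> np.ndarray:
    """Evaluate the truncated series at ``n_points`` uniform parameter
    values over one period (t normalized to [0, 1))."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    tau = np.arange(n_points) / n_points  # [0, 1)
    k = np.arange(1, model.order + 1)[:, None]
    ang = 2.0 * np.pi * k * tau[None, :]  # (K, n)
    cos, sin = np.cos(ang), np.sin(ang)
    a, b, c, d = (model.coeffs[:, j][:, None] for j in range(4))
    x = model.a0 + np.sum(a * cos + b * sin, axis=0)
    y = model.c0 + np.sum(c * cos + d * sin, axis=0)
    return np.column_stack([x, y])


def param_count(order: int, include_constants: bool = False) -> int:
    """Number of model parameters: 4K shape parameters, +2 with a0, c0."""
    if order < 1:
        raise ValueError("order must be >= 1")
    return 4 * order + (2 if include_constants else 0)
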
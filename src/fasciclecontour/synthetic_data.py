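"""Synthetic fascicle-contour generator.

Real fascicle cross-section datasets come from MicroCT imaging of nerve
specimens and are not redistributable, so the test bed is synthetic:
4th-order Fourier models are drawn parameter-by-parameter from the
population laws fitted to a large fascicle dataset, reconstructed into
closed contours, screened for geometric validity, and rasterized into
binary masks.

Population laws (pixel units):

* fundamental amplitudes a1 and d1 — multimodal; hard-interval Gaussian
  component tables with 3 (a1) and 4 (d1) components.  The published
  component tables carry no mixture weights, so sampling uses equal
  weights, truncated to x > 0 (the amplitudes set the fascicle caliber);
* b3 — normal N(0.03, 0.46^2);
* the fundamental b1, c1 and every remaining harmonic — t location-scale
  with per-parameter (mu, sigma, nu);
* a0 = c0 = 0 (contours are generated in the centered frame).

Parameters are drawn independently: only the marginal laws are known,
the joint dependence structure is not (a documented limitation — real
fascicles correlate e.g. a1 with d1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing, Polygon

from .fourier_efd import FourierModel, efd_reconstruct
from .metrics import rasterize

__all__ = [
    "DistSpec",
    "SyntheticDataset",
    "DEFAULT_SPEC",
    "sample_model",
    "generate_contour",
    "generate_dataset",
    "make_fixtures",
    "ContourRejected",
    "A1_COMPONENTS",
    "D1_COMPONENTS",
    "B3_LAW",
    "T_LAWS",
]

# Gaussian component tables for the fundamental amplitudes: (lo, hi, mu, sigma).
# Sigmas recovered from the published prefactors 1/(sigma sqrt(2 pi)) and
# exponent denominators 2 sigma^2.
A1_COMPONENTS = (
    (0.0, 25.0, 14.11, 5.0),
    (25.0, 50.0, 36.51, 6.68),
    (50.0, np.inf, 58.15, 3.86),
)
D1_COMPONENTS = (
    (0.0, 25.0, 14.40, 4.44),
    (25.0, 33.0, 29.99, 1.77),
    (33.0, 50.0, 41.57, 4.41),
    (50.0, np.inf, 59.15, 3.75),
)

B3_LAW = (0.03, 0.46)  # mean, sd

# t location-scale laws (mu, sigma, nu) for the remaining 12 shape parameters.
T_LAWS = {
    "a2": (-0.08, 0.66, 5.43),
    "a3": (-0.05, 0.49, 5.70),
    "a4": (0.01, 0.36, 7.17),
    "b1": (2.36, 4.45, 2.85),
    "b2": (-0.03, 0.49, 2.62),
    "b4": (0.02, 0.40, 4.84),
    "c1": (-2.67, 4.48, 3.45),
    "c2": (0.02, 0.47, 2.37),
    "c3": (0.02, 0.47, 16.71),
    "c4": (-0.01, 0.30, 3.18),
    "d2": (0.04, 0.62, 4.44),
    "d3": (0.18, 0.40, 5.39),
    "d4": (0.11, 0.36, 4.33),
}


class ContourRejected(Exception):
    """A sampled model produced a geometrically invalid contour."""


@dataclass(frozen=True)
class DistSpec:
    """Per-parameter law assignment for sampling 4th-order models."""

    a1_components: tuple = A1_COMPONENTS
    d1_components: tuple = D1_COMPONENTS
    b3_law: tuple = B3_LAW
    t_laws: dict = field(default_factory=lambda: dict(T_LAWS))


DEFAULT_SPEC = DistSpec()


def _sample_mixture(components, rng: np.random.Generator) -> float:
    """Equal-weight Gaussian mixture draw, truncated to x > 0."""
    for _ in range(1000):
        _lo, _hi, mu, sigma = components[rng.integers(len(components))]
        x = rng.normal(mu, sigma)
        if x > 0:
            return float(x)
    raise RuntimeError("mixture truncation failed to accept a draw")


def sample_model(spec: DistSpec = DEFAULT_SPEC, seed=None) -> FourierModel:
    """Draw one 4th-order Fourier model from the population laws.

    ``seed`` may be an int or a numpy Generator; all 16 shape parameters
    are drawn independently and a0 = c0 = 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vals = {"a1": _sample_mixture(spec.a1_components, rng),
            "d1": _sample_mixture(spec.d1_components, rng),
            "b3": float(rng.normal(*spec.b3_law))}
    for name, (mu, sigma, nu) in spec.t_laws.items():
        vals[name] = float(mu + sigma * rng.standard_t(nu))
    coeffs = np.array([[vals[f"a{k}"], vals[f"b{k}"], vals[f"c{k}"], vals[f"d{k}"]]
                       for k in range(1, 5)])
    return FourierModel(order=4, a0=0.0, c0=0.0, coeffs=coeffs)


def generate_contour(model: FourierModel, n_points: int = 400,
                     min_area: float = 50.0, pad_frac: float = 0.1
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a model into a validated contour and its mask.

    The contour must be simple (no self-intersection) and enclose at
    least ``min_area`` pixels; otherwise :class:`ContourRejected` is
    raised and the caller resamples.  The mask grid pads the bounding box
    by ``pad_frac`` on each side.

    Returns ``(contour, mask)``; the contour is in the mask's math frame
    (x = col, y = -row), i.e. already translated onto the grid.
    """
    contour = efd_reconstruct(model, n_points)
    try:
        ring = LinearRing(contour)
    except Exception as err:
        raise ContourRejected(f"degenerate contour: {err}") from None
    if not ring.is_simple:
        raise ContourRejected("self-intersecting contour")
    area = Polygon(ring).area
    if area < min_area:
        raise ContourRejected(f"area {area:.1f} px below minimum {min_area}")

    x0, y0 = contour.min(axis=0)
    x1, y1 = contour.max(axis=0)
    # half-pixel in the padding keeps symmetric shapes off exact
    # lattice-point centers, where boundary ties bias the pixel count
    pad = pad_frac * max(x1 - x0, y1 - y0) + 2.5
    # place on a grid: x -> col, y -> -row
    shifted = contour - [x0 - pad, y1 + pad]  # x >= pad, y <= -pad
    shape = (int(np.ceil((y1 - y0) + 2 * pad)) + 1,
             int(np.ceil((x1 - x0) + 2 * pad)) + 1)
    pixels = np.column_stack([shifted[:, 0], -shifted[:, 1]])
    mask = rasterize(pixels, shape)
    return shifted, mask


@dataclass(frozen=True)
class SyntheticDataset:
    """Accepted synthetic contours with their ground-truth models."""

    contours: list = field(repr=False)
    masks: list = field(repr=False)
    models: list = field(repr=False)
    seed: int | None = None
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.contours)


def generate_dataset(n: int, spec: DistSpec = DEFAULT_SPEC, seed=None,
                     n_points: int = 400) -> SyntheticDataset:
    """Rejection-sample ``n`` valid synthetic fascicle contours.

    Aborts with a diagnostic if more than 90% of draws are rejected.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    contours, masks, models = [], [], []
    rejected = 0
    while len(contours) < n:
        model = sample_model(spec, rng)
        try:
            contour, mask = generate_contour(model, n_points=n_points)
        except ContourRejected:
            rejected += 1
            total = rejected + len(contours)
            if total >= 50 and rejected / total > 0.9:
                raise RuntimeError(
                    f"rejection rate {rejected}/{total} exceeds 90%; "
                    "check the distribution spec") from None
            continue
        contours.append(contour)
        masks.append(mask)
        models.append(model)
    return SyntheticDataset(contours=contours, masks=masks, models=models,
                            seed=seed if isinstance(seed, int) else None,
                            n_rejected=rejected)


def make_fixtures(n_points: int = 400) -> dict[str, dict]:
    """Deterministic analytic shapes with known geometry for oracle tests.

    Returns a dict name -> {contour, mask, area, perimeter} with the
    analytic (pre-rasterization) area and perimeter.  Shapes: circle of
    radius 20, a 20x10-semi-axis ellipse, a rounded square, and a
    five-lobed star (high harmonic content).
    """
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    out: dict[str, dict] = {}

    def add(name, x, y, area, perimeter):
        contour = np.column_stack([x, y])
        x0, y0 = contour.min(axis=0)
        y1 = contour.max(axis=0)[1]
        pad = 3.0
        shifted = contour - [x0 - pad, y1 + pad]
        shape = (int(np.ceil(np.ptp(contour[:, 1]) + 2 * pad)) + 1,
                 int(np.ceil(np.ptp(contour[:, 0]) + 2 * pad)) + 1)
        pixels = np.column_stack([shifted[:, 0], -shifted[:, 1]])
        out[name] = {"contour": shifted, "mask": rasterize(pixels, shape),
                     "area": area, "perimeter": perimeter}

    r = 20.0
    add("circle", r * np.cos(theta), r * np.sin(theta),
        np.pi * r**2, 2 * np.pi * r)

    a, b = 20.0, 10.0
    add("ellipse", a * np.cos(theta), b * np.sin(theta),
        np.pi * a * b, _ellipse_perimeter(a, b))

    # rounded square: superellipse |x/s|^4 + |y/s|^4 = 1
    s = 18.0
    denom = (np.abs(np.cos(theta)) ** 4 + np.abs(np.sin(theta)) ** 4) ** 0.25
    xs, ys = s * np.cos(theta) / denom, s * np.sin(theta) / denom
    add("rounded_square", xs, ys, _polygon_area(xs, ys), _polygon_perimeter(xs, ys))

    # five-lobed star: r(theta) = 20 + 6 cos(5 theta)
    rad = 20.0 + 6.0 * np.cos(5 * theta)
    xs, ys = rad * np.cos(theta), rad * np.sin(theta)
    add("star", xs, ys, _polygon_area(xs, ys), _polygon_perimeter(xs, ys))
    return out


def _ellipse_perimeter(a: float, b: float) -> float:
    from scipy.special import ellipe

    e2 = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(e2))


def _polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _polygon_perimeter(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.hypot(np.roll(x, -1) - x, np.roll(y, -1) - y).sum())
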
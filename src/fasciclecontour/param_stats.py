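"""Statistical laws of the Fourier model parameters.

Across a population of fascicle contours the 4th-order model yields 18
parameters per contour (a0, a1..a4, b1..b4, c0, c1..c4, d1..d4).  The
fundamental amplitudes a1 and d1 are multimodal (fascicle calibers fall
into a few size groups) and are described by Gaussian mixtures; most of
the remaining shape parameters are sharply peaked and heavy-tailed and
follow t location-scale laws; b3 is well described by a plain normal.

This module collects the parameter table, fits the candidate families
(normal, logistic, t location-scale by maximum likelihood; Gaussian
mixtures by EM) and picks among them by BIC.  A piecewise hard-boundary
mixture evaluator is also provided: it reproduces published piecewise
density tables in which each support interval carries a single Gaussian
component; that form is not a normalized density in general.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .fourier_efd import FourierModel

__all__ = [
    "PARAM_COLUMNS",
    "DistributionFit",
    "collect_params",
    "fit_normal",
    "fit_logistic",
    "fit_t_locscale",
    "fit_gmm",
    "best_fit",
    "pdf_piecewise_mixture",
]

PARAM_COLUMNS = (
    ["a0"] + [f"a{k}" for k in range(1, 5)] + [f"b{k}" for k in range(1, 5)]
    + ["c0"] + [f"c{k}" for k in range(1, 5)] + [f"d{k}" for k in range(1, 5)]
)

_MIN_SAMPLES = 30


@dataclass(frozen=True)
class DistributionFit:
    """A fitted probability law for one model parameter.

    ``params`` holds the family's natural parameters:
      normal / logistic: mu, sigma
      t_locscale: mu, sigma, nu (degrees of freedom)
      gmm: weights, means, sigmas (components sorted by mean)
    """

    kind: str
    params: dict = field(default_factory=dict)
    loglik: float = np.nan
    bic: float = np.nan
    n: int = 0
    candidates: dict = field(default_factory=dict)  # kind -> (loglik, bic)

    def pdf(self, x):
        scalar = np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=float))
        p = self.params
        if self.kind == "normal":
            out = stats.norm.pdf(x, p["mu"], p["sigma"])
        elif self.kind == "logistic":
            out = stats.logistic.pdf(x, p["mu"], p["sigma"])
        elif self.kind == "t_locscale":
            out = stats.t.pdf(x, p["nu"], p["mu"], p["sigma"])
        elif self.kind == "gmm":
            w = np.asarray(p["weights"])[:, None]
            mu = np.asarray(p["means"])[:, None]
            sd = np.asarray(p["sigmas"])[:, None]
            out = np.sum(w * stats.norm.pdf(x[None, :], mu, sd), axis=0)
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        return float(out[0]) if scalar else out

    def n_params(self) -> int:
        if self.kind in ("normal", "logistic"):
            return 2
        if self.kind == "t_locscale":
            return 3
        if self.kind == "gmm":
            return 3 * len(self.params["weights"]) - 1
        raise ValueError(self.kind)


def collect_params(models: Sequence[FourierModel]) -> pd.DataFrame:
    """Stack the 18 parameters of a set of order-4 models into a table,
    one row per contour model."""
    models = list(models)
    if not models:
        raise ValueError("no models given")
    orders = {m.order for m in models}
    if orders != {4}:
        raise ValueError(f"all models must share order 4, got orders {sorted(orders)}")
    rows = [m.param_vector(include_constants=True) for m in models]
    return pd.DataFrame(rows, columns=PARAM_COLUMNS)


def _check_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < _MIN_SAMPLES:
        import warnings

        warnings.warn(f"only {x.size} samples; fits below n={_MIN_SAMPLES} are unreliable",
                      stacklevel=3)
    if x.size and np.ptp(x) == 0:
        raise ValueError("constant samples: scale parameter would be zero")
    return x


def _make_fit(kind: str, params: dict, loglik: float, n: int, k: int) -> DistributionFit:
    bic = k * np.log(n) - 2.0 * loglik
    return DistributionFit(kind=kind, params=params, loglik=loglik, bic=bic, n=n)


def fit_normal(samples) -> DistributionFit:
    """Maximum-likelihood normal fit (mu = mean, sigma = MLE std)."""
    x = _check_samples(samples)
    mu, sigma = stats.norm.fit(x)
    ll = float(stats.norm.logpdf(x, mu, sigma).sum())
    return _make_fit("normal", {"mu": float(mu), "sigma": float(sigma)}, ll, x.size, 2)


def fit_logistic(samples) -> DistributionFit:
    """Maximum-likelihood logistic location/scale fit."""
    x = _check_samples(samples)
    mu, sigma = stats.logistic.fit(x)
    ll = float(stats.logistic.logpdf(x, mu, sigma).sum())
    return _make_fit("logistic", {"mu": float(mu), "sigma": float(sigma)}, ll, x.size, 2)


def fit_t_locscale(samples) -> DistributionFit:
    """Maximum-likelihood t location-scale fit (mu, sigma, nu).

    The density is the location-scale transform of the Student t:
    f(x) = Gamma((nu+1)/2) / (sigma sqrt(nu pi) Gamma(nu/2))
           * (1 + ((x-mu)/sigma)^2 / nu)^(-(nu+1)/2).
    """
    x = _check_samples(samples)
    nu, mu, sigma = stats.t.fit(x)
    if not (np.isfinite([nu, mu, sigma]).all() and nu > 0 and sigma > 0):
        raise RuntimeError(f"t location-scale MLE did not converge: nu={nu}, mu={mu}, sigma={sigma}")
    ll = float(stats.t.logpdf(x, nu, mu, sigma).sum())
    return _make_fit("t_locscale",
                     {"mu": float(mu), "sigma": float(sigma), "nu": float(nu)},
                     ll, x.size, 3)


def fit_gmm(samples, n_components: int, seed: int | None = 0) -> DistributionFit:
    """EM-fitted Gaussian mixture; components reported sorted by mean."""
    x = _check_samples(samples)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if x.size < _MIN_SAMPLES * n_components:
        import warnings

        warnings.warn("fewer than 30 samples per mixture component", stacklevel=2)
    gm = GaussianMixture(n_components=n_components, covariance_type="full",
                         random_state=seed, n_init=3, reg_covar=1e-10)
    gm.fit(x[:, None])
    sigmas = np.sqrt(gm.covariances_.ravel())
    if np.any(sigmas < 1e-8 * max(np.ptp(x), 1.0)):
        raise RuntimeError("EM produced a degenerate (zero-variance) component")
    order = np.argsort(gm.means_.ravel())
    params = {
        "weights": gm.weights_.ravel()[order].tolist(),
        "means": gm.means_.ravel()[order].tolist(),
        "sigmas": sigmas[order].tolist(),
    }
    ll = float(gm.score(x[:, None]) * x.size)
    return _make_fit("gmm", params, ll, x.size, 3 * n_components - 1)


_FITTERS = {
    "normal": fit_normal,
    "logistic": fit_logistic,
    "t_locscale": fit_t_locscale,
}


def best_fit(samples, candidates: Sequence = ("normal", "logistic", "t_locscale"),
             seed: int | None = 0) -> DistributionFit:
    """Fit every candidate family and return the one minimizing BIC.

    Candidates are family names; a Gaussian mixture with m components is
    requested as ``("gmm", m)``.  All candidates' scores are retained in
    the winner's ``candidates`` attribute.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate families")
    fits: dict[str, DistributionFit] = {}
    errors: dict[str, Exception] = {}
    for cand in candidates:
        try:
            if isinstance(cand, (tuple, list)):
                kind, m = cand
                if kind != "gmm":
                    raise ValueError(f"unknown candidate {cand!r}")
                fits[f"gmm{m}"] = fit_gmm(samples, m, seed=seed)
            elif cand == "gmm":
                fits["gmm3"] = fit_gmm(samples, 3, seed=seed)
            else:
                fits[cand] = _FITTERS[cand](samples)
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            errors[str(cand)] = err
    if not fits:
        raise RuntimeError(f"all candidate fits failed: {errors}")
    scores = {name: (f.loglik, f.bic) for name, f in fits.items()}
    winner = min(fits, key=lambda name: fits[name].bic)
    best = fits[winner]
    return DistributionFit(kind=best.kind, params=best.params, loglik=best.loglik,
                           bic=best.bic, n=best.n, candidates=scores)


def pdf_piecewise_mixture(x, spec: Sequence[tuple]) -> np.ndarray:
    """Evaluate a piecewise hard-boundary Gaussian table.

    ``spec`` is a list of ``(lo, hi, mu, sigma)`` entries whose [lo, hi)
    intervals must partition the support without overlap (hi = inf on the
    last piece); on each interval the value is the normal pdf of that
    interval's component.  The total is generally NOT a normalized
    density — it reproduces published piecewise density tables verbatim
    (with the exponent sign taken negative).
    """
    spec = sorted(spec, key=lambda s: s[0])
    for (lo1, hi1, *_), (lo2, _hi2, *_) in zip(spec, spec[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping intervals: [{lo1}, {hi1}) and [{lo2}, ...)")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for lo, hi, mu, sigma in spec:
        sel = (x >= lo) & (x < hi)
        out[sel] = stats.norm.pdf(x[sel], mu, sigma)
    return out if out.size > 1 else float(out[0])
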
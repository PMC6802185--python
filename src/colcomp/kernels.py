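"""Radially symmetric seed-dispersal kernels.

A dispersal kernel ``P(r)`` is the probability density, per unit area of
ground, that a seed comes to rest at distance ``r`` from its mother.  Four
two-dimensional families are supported, the candidates routinely compared in
inverse models of seed shadows:

``negative_exponential``
    ``P(r) = exp(-r/b) / (2 pi b^2)``, scale ``b`` in meters.
``two_dim_t``
    ``P(r) = p / (pi u) * (1 + r^2/u)^-(p+1)``, scale ``u`` in m^2 and
    dimensionless shape ``p``; a fat-tailed Student-t analogue.
``lognormal``
    ``P(r) = exp(-(ln(r/a))^2 / (2 b^2)) / ((2 pi)^{3/2} b r^2)``; the radial
    distance is lognormal with median ``a`` (m) and log-scale ``b``.
``weibull``
    ``P(r) = c / (2 pi a^c) * r^(c-2) * exp(-(r/a)^c)``; the radial distance
    is Weibull with scale ``a`` (m) and shape ``c``.

Each family satisfies the 2-D normalization ``int_0^inf 2 pi r P(r) dr = 1``:
the radial integrand ``2 pi r P(r)`` is, respectively, a Gamma(2, b),
a generalized-Pareto-in-``r^2``, a lognormal, and a Weibull density, so the
radial distance distribution has closed-form CDF and quantiles throughout.
The lognormal density is defined as 0 at r = 0 (its limit), and the Weibull
density with shape ``c < 2`` diverges pointwise at the origin while remaining
integrable; all integrals here therefore go through the radial CDF, never the
raw density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "FAMILIES",
    "KernelSpec",
    "kernel_density",
    "radial_cdf",
    "radial_ppf",
    "long_distance_dispersal",
    "sample_distances",
    "sample_positions",
]

#: Canonical family order; also the tie-break order in model selection.
FAMILIES = ("negative_exponential", "two_dim_t", "lognormal", "weibull")

_N_PARAMS = {
    "negative_exponential": 1,
    "two_dim_t": 2,
    "lognormal": 2,
    "weibull": 2,
}


class InvalidKernelError(ValueError):
    """Raised for unknown families or non-positive parameters."""


@dataclass(frozen=True)
class KernelSpec:
    """A dispersal kernel family together with its positive parameters.

    Parameters are ordered ``(b1,)`` or ``(b1, b2)``:

    ======================  =========  ==================================
    family                  b1         b2
    ======================  =========  ==================================
    negative_exponential    scale b    --
    two_dim_t               scale u    shape p
    lognormal               median a   log-scale b
    weibull                 scale a    shape c
    ======================  =========  ==================================
    """

    family: str
    params: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidKernelError(
                f"unknown kernel family {self.family!r}; expected one of {FAMILIES}"
            )
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[self.family]:
            raise InvalidKernelError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameter(s), "
                f"got {len(params)}"
            )
        if not all(math.isfinite(p) and p > 0 for p in params):
            raise InvalidKernelError(
                f"kernel parameters must be finite and strictly positive, got {params}"
            )

    @property
    def n_params(self) -> int:
        return len(self.params)

    def to_json(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_json(cls, obj: dict | str) -> "KernelSpec":
        if isinstance(obj, str):
            obj = json.loads(obj)
        return cls(family=obj["family"], params=tuple(obj["params"]))


def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    return r


def kernel_density(spec: KernelSpec, r) -> np.ndarray | float:
    """Seed deposition density P(r) per m^2 at distance ``r`` (m).

    The lognormal density at r = 0 is its limit, 0; the Weibull density with
    shape < 2 is +inf at r = 0 (integrable singularity).
    """
    r = _check_r(r)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    out = np.empty_like(r)
    if spec.family == "negative_exponential":
        (b,) = spec.params
        out = np.exp(-r / b) / (2 * np.pi * b * b)
    elif spec.family == "two_dim_t":
        u, p = spec.params
        out = p / (np.pi * u) * (1 + r * r / u) ** (-(p + 1))
    elif spec.family == "lognormal":
        a, b = spec.params
        out = np.zeros_like(r)
        pos = r > 0
        rp = r[pos]
        out[pos] = np.exp(-((np.log(rp / a)) ** 2) / (2 * b * b)) / (
            (2 * np.pi) ** 1.5 * b * rp * rp
        )
    else:  # weibull
        a, c = spec.params
        out = np.zeros_like(r)
        pos = r > 0
        rp = r[pos]
        out[pos] = (
            c / (2 * np.pi * a**c) * rp ** (c - 2) * np.exp(-((rp / a) ** c))
        )
        zero = ~pos
        if np.any(zero):
            if c < 2:
                out[zero] = np.inf
            elif c == 2:
                out[zero] = 1.0 / (np.pi * a * a)
            else:
                out[zero] = 0.0
    return float(out[0]) if scalar else out


def radial_cdf(spec: KernelSpec, r) -> np.ndarray | float:
    """Probability that the dispersal distance is <= ``r``:
    ``int_0^r 2 pi s P(s) ds`` in closed form."""
    r = _check_r(r)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if spec.family == "negative_exponential":
        (b,) = spec.params
        x = r / b
        out = -np.expm1(-x) - x * np.exp(-x)  # 1 - (1+x) e^{-x}
    elif spec.family == "two_dim_t":
        u, p = spec.params
        out = 1.0 - (1.0 + r * r / u) ** (-p)
    elif spec.family == "lognormal":
        a, b = spec.params
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = 0.5 * (1 + special.erf(np.log(r[pos] / a) / (b * math.sqrt(2))))
    else:  # weibull
        a, c = spec.params
        out = -np.expm1(-((r / a) ** c))
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def radial_ppf(spec: KernelSpec, q) -> np.ndarray | float:
    """Quantile function of the radial distance (inverse of radial_cdf)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile level must lie in [0, 1]")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if spec.family == "negative_exponential":
        (b,) = spec.params
        # Gamma(2, b) quantile; no elementary inverse.
        out = b * special.gammaincinv(2.0, q)
    elif spec.family == "two_dim_t":
        u, p = spec.params
        out = np.sqrt(u * ((1.0 - q) ** (-1.0 / p) - 1.0))
    elif spec.family == "lognormal":
        a, b = spec.params
        out = a * np.exp(b * math.sqrt(2) * special.erfinv(2 * q - 1))
    else:  # weibull
        a, c = spec.params
        out = a * (-np.log1p(-q)) ** (1.0 / c)
    return float(out[0]) if scalar else out


def long_distance_dispersal(spec: KernelSpec, threshold: float = 50.0) -> float:
    """Probability of dispersal beyond ``threshold`` meters (default 50 m),
    ``LDD = 1 - int_0^threshold 2 pi r P(r) dr``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(1.0 - radial_cdf(spec, threshold))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_distances(spec: KernelSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. radial dispersal distances."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if spec.family == "negative_exponential":
        (b,) = spec.params
        return rng.gamma(shape=2.0, scale=b, size=n)
    if spec.family == "two_dim_t":
        u, p = spec.params
        q = rng.random(n)
        return np.sqrt(u * ((1.0 - q) ** (-1.0 / p) - 1.0))
    if spec.family == "lognormal":
        a, b = spec.params
        return rng.lognormal(mean=np.log(a), sigma=b, size=n)
    a, c = spec.params
    return a * rng.weibull(c, size=n)


def sample_positions(spec: KernelSpec, origin, n: int, seed) -> np.ndarray:
    """Sample ``n`` seed landing positions around ``origin = (x, y)``.

    Distances follow the kernel's radial CDF; directions are uniform on
    [0, 2 pi).  Returns an (n, 2) array.  A fixed integer seed makes the
    output reproducible.
    """
    rng = _as_rng(seed)
    r = sample_distances(spec, n, rng)
    theta = rng.uniform(0.0, 2 * np.pi, size=n)
    ox, oy = float(origin[0]), float(origin[1])
    return np.column_stack((ox + r * np.cos(theta), oy + r * np.sin(theta)))
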
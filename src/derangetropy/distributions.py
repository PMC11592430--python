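"""Distribution families and empirical density estimation.

Every downstream operation in this package consumes a :class:`DistributionSpec`:
a mutually consistent (pdf, cdf) pair on a stated support, together with the
median.  Five analytic families are provided — uniform, normal, exponential,
Wigner semicircle and arcsin — plus a kernel-density estimate built from raw
samples.  The analytic families wrap frozen ``scipy.stats`` distributions; the
closed-form density derivative needed for the derangetropy derivative is
attached per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .exceptions import (
    DegenerateSampleError,
    InvalidInputError,
    InvalidParameterError,
    UnsupportedFamilyError,
)

__all__ = [
    "DistributionSpec",
    "make_distribution",
    "empirical_distribution",
    "evaluation_grid",
    "read_samples",
    "FAMILIES",
]

#: Tail probability used to truncate unbounded supports for grid evaluation.
TAIL_PROB = 1e-6

#: Convergence tolerance (in CDF units) for the median bisection.
MEDIAN_TOL = 1e-12


@dataclass(frozen=True)
class DistributionSpec:
    """An evaluable density/CDF pair on a stated support.

    Parameters
    ----------
    name
        Family label (``"uniform"``, ``"normal"``, ..., or ``"empirical"``).
    params
        Family parameters as given by the caller (empty for empirical).
    support
        ``(lower, upper)`` interval; either end may be infinite.
    pdf, cdf
        Vectorized evaluators.  ``pdf(x) >= 0``; ``cdf`` is non-decreasing
        with ``cdf(lower) = 0`` and ``cdf(upper) = 1``.
    median
        The root of ``cdf(m) = 0.5``, located by bisection.
    ppf
        Quantile function (inverse CDF); used for grid construction on
        unbounded supports.
    pdf_deriv
        Derivative of the density, closed form for analytic families and a
        central difference for empirical estimates.
    """

    name: str
    params: tuple
    support: tuple
    pdf: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    cdf: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    median: float
    ppf: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, repr=False
    )
    pdf_deriv: Optional[Callable[[np.ndarray], np.ndarray]] = field(
        default=None, repr=False
    )


def _median_by_bisection(cdf, lo: float, hi: float) -> float:
    """Bisect ``cdf(m) = 0.5`` on [lo, hi] to within MEDIAN_TOL in F."""
    flo, fhi = cdf(lo) - 0.5, cdf(hi) - 0.5
    if flo > 0 or fhi < 0:
        raise InvalidParameterError(
            f"median bracket [{lo}, {hi}] does not straddle F = 0.5"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = cdf(mid) - 0.5
        if abs(fmid) < MEDIAN_TOL:
            return mid
        if fmid < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-15 * max(1.0, abs(mid)):
            break
    return 0.5 * (lo + hi)


def _finite_bracket(frozen, lo: float, hi: float) -> tuple[float, float]:
    """A finite bracket for the median when the support is unbounded."""
    blo = lo if np.isfinite(lo) else float(frozen.ppf(1e-9))
    bhi = hi if np.isfinite(hi) else float(frozen.ppf(1 - 1e-9))
    return blo, bhi


def _spec_from_frozen(name, params, frozen, support, pdf_deriv) -> DistributionSpec:
    lo, hi = support
    pdf = lambda x: np.asarray(frozen.pdf(x), dtype=float)  # noqa: E731
    cdf = lambda x: np.asarray(frozen.cdf(x), dtype=float)  # noqa: E731
    median = _median_by_bisection(
        lambda m: float(frozen.cdf(m)), *_finite_bracket(frozen, lo, hi)
    )
    return DistributionSpec(
        name=name,
        params=tuple(params),
        support=(float(lo), float(hi)),
        pdf=pdf,
        cdf=cdf,
        median=float(median),
        ppf=lambda q: np.asarray(frozen.ppf(q), dtype=float),
        pdf_deriv=pdf_deriv,
    )


def _make_uniform(a: float, b: float) -> DistributionSpec:
    if not a < b:
        raise InvalidParameterError(f"uniform requires a < b, got ({a}, {b})")
    frozen = stats.uniform(loc=a, scale=b - a)
    return _spec_from_frozen(
        "uniform", (a, b), frozen, (a, b), lambda x: np.zeros_like(np.asarray(x, float))
    )


def _make_normal(mu: float, sigma: float) -> DistributionSpec:
    if sigma <= 0:
        raise InvalidParameterError(f"normal requires sigma > 0, got {sigma}")
    frozen = stats.norm(loc=mu, scale=sigma)

    def dpdf(x):
        x = np.asarray(x, float)
        return -(x - mu) / sigma**2 * frozen.pdf(x)

    return _spec_from_frozen("normal", (mu, sigma), frozen, (-np.inf, np.inf), dpdf)


def _make_exponential(rate: float) -> DistributionSpec:
    if rate <= 0:
        raise InvalidParameterError(f"exponential requires rate > 0, got {rate}")
    frozen = stats.expon(scale=1.0 / rate)

    def dpdf(x):
        x = np.asarray(x, float)
        return np.where(x >= 0, -rate * frozen.pdf(x), 0.0)

    return _spec_from_frozen("exponential", (rate,), frozen, (0.0, np.inf), dpdf)


def _make_semicircle(a: float, b: float) -> DistributionSpec:
    # Wigner semicircle on (a, b): density ∝ sqrt(R² − (x − c)²), R = (b−a)/2.
    if not a < b:
        raise InvalidParameterError(f"semicircle requires a < b, got ({a}, {b})")
    c, R = 0.5 * (a + b), 0.5 * (b - a)
    frozen = stats.semicircular(loc=c, scale=R)

    def dpdf(x):
        u = np.asarray(x, float) - c
        inside = np.abs(u) < R
        out = np.zeros_like(u)
        root = np.sqrt(np.clip(R**2 - u**2, 1e-300, None))
        out[inside] = (-2.0 / (np.pi * R**2) * u / root)[inside]
        return out

    return _spec_from_frozen("semicircle", (a, b), frozen, (a, b), dpdf)


def _make_arcsin(a: float, b: float) -> DistributionSpec:
    # Arcsin law on (a, b): F(x) = (2/π)·arcsin(√((x−a)/(b−a))).
    if not a < b:
        raise InvalidParameterError(f"arcsin requires a < b, got ({a}, {b})")
    frozen = stats.arcsine(loc=a, scale=b - a)

    def dpdf(x):
        x = np.asarray(x, float)
        inside = (x > a) & (x < b)
        out = np.zeros_like(x)
        f = frozen.pdf(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = f * (-0.5) * (1.0 / (x - a) - 1.0 / (b - x))
        out[inside] = val[inside]
        return out

    return _spec_from_frozen("arcsin", (a, b), frozen, (a, b), dpdf)


FAMILIES = {
    "uniform": (_make_uniform, 2),
    "normal": (_make_normal, 2),
    "exponential": (_make_exponential, 1),
    "semicircle": (_make_semicircle, 2),
    "arcsin": (_make_arcsin, 2),
}


def make_distribution(name: str, params: Sequence[float]) -> DistributionSpec:
    """Construct one of the five analytic families.

    Parameters
    ----------
    name
        One of ``uniform(a, b)``, ``normal(mu, sigma)``, ``exponential(rate)``,
        ``semicircle(a, b)`` (interval endpoints; radius = (b−a)/2) and
        ``arcsin(a, b)``.
    params
        The family parameters, in the order above.
    """
    key = name.lower()
    if key not in FAMILIES:
        raise UnsupportedFamilyError(
            f"unknown family {name!r}; supported: {sorted(FAMILIES)}"
        )
    maker, nparams = FAMILIES[key]
    params = tuple(float(p) for p in params)
    if len(params) != nparams:
        raise InvalidParameterError(
            f"{key} takes {nparams} parameter(s), got {len(params)}"
        )
    return maker(*params)


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Robust Silverman rule of thumb: 0.9·min(sd, IQR/1.34)·n^(−1/5)."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * len(x) ** (-0.2)


def empirical_distribution(
    samples: Sequence[float], bandwidth="silverman"
) -> DistributionSpec:
    """Gaussian-KDE density with a mutually consistent integrated CDF.

    The density is the Gaussian-mixture KDE truncated to the extended support
    ``(min − 3h, max + 3h)`` and renormalized; the CDF is the exact integral
    of that same truncated density (closed form via the normal CDF), so the
    pair satisfies every :class:`DistributionSpec` invariant: the CDF is 0 and
    1 exactly at the support edges and the density integrates to one.

    Parameters
    ----------
    samples
        At least 10 finite reals with positive variance.
    bandwidth
        Kernel standard deviation ``h``; a positive number, or
        ``"silverman"`` for the robust Silverman rule of thumb.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("samples must be a one-dimensional sequence")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("samples contain non-finite values")
    if x.size < 10:
        raise DegenerateSampleError(f"need at least 10 samples, got {x.size}")
    if np.var(x) == 0:
        raise DegenerateSampleError("sample variance is zero")

    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise InvalidParameterError(f"unknown bandwidth rule {bandwidth!r}")
        h = _silverman_bandwidth(x)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise InvalidParameterError(f"bandwidth must be positive, got {h}")

    lo = float(x.min() - 3 * h)
    hi = float(x.max() + 3 * h)
    centers = np.sort(x)
    n = centers.size

    def _mix_cdf(t: np.ndarray) -> np.ndarray:
        # mean of Φ((t − x_i)/h), chunked over t to bound memory
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        step = max(1, int(4e6 // n))
        for i in range(0, t.size, step):
            out[i : i + step] = ndtr(
                (t[i : i + step, None] - centers[None, :]) / h
            ).mean(axis=1)
        return out

    def _mix_pdf(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t)
        step = max(1, int(4e6 // n))
        inv = 1.0 / (h * np.sqrt(2 * np.pi))
        for i in range(0, t.size, step):
            z = (t[i : i + step, None] - centers[None, :]) / h
            out[i : i + step] = inv * np.exp(-0.5 * z**2).mean(axis=1)
        return out

    c_lo = float(_mix_cdf(np.array([lo]))[0])
    mass = float(_mix_cdf(np.array([hi]))[0]) - c_lo  # ≈ 0.9973 before truncation

    def pdf(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        inside = (t >= lo) & (t <= hi)
        out = np.zeros_like(t)
        if inside.any():
            out[inside] = _mix_pdf(t[inside]) / mass
        return out if out.size > 1 else out.reshape(())

    def cdf(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.clip((_mix_cdf(t) - c_lo) / mass, 0.0, 1.0)
        out[t <= lo] = 0.0
        out[t >= hi] = 1.0
        return out if out.size > 1 else out.reshape(())

    def ppf(q):
        q = np.atleast_1d(np.asarray(q, dtype=float))
        out = np.empty_like(q)
        for i, qi in enumerate(q):
            a, b = lo, hi
            for _ in range(100):
                mid = 0.5 * (a + b)
                if float(cdf(mid)) < qi:
                    a = mid
                else:
                    b = mid
            out[i] = 0.5 * (a + b)
        return out if out.size > 1 else out.reshape(())

    def pdf_deriv(t):
        eps = 1e-4 * h
        return (pdf(np.asarray(t, float) + eps) - pdf(np.asarray(t, float) - eps)) / (
            2 * eps
        )

    median = _median_by_bisection(lambda m: float(cdf(m)), lo, hi)
    return DistributionSpec(
        name="empirical",
        params=(float(h),),
        support=(lo, hi),
        pdf=pdf,
        cdf=cdf,
        median=float(median),
        ppf=ppf,
        pdf_deriv=pdf_deriv,
    )


def evaluation_grid(dist: DistributionSpec, n_points: int) -> np.ndarray:
    """Strictly increasing evaluation points covering the bulk of the support.

    Bounded supports get ``n_points`` equally spaced *interior* points;
    unbounded (or half-bounded) supports are truncated to the quantile
    interval ``[F⁻¹(1e−6), F⁻¹(1 − 1e−6)]`` discretized inclusively.
    """
    if n_points < 3:
        raise InvalidParameterError(f"n_points must be >= 3, got {n_points}")
    lo, hi = dist.support
    if np.isfinite(lo) and np.isfinite(hi):
        return np.linspace(lo, hi, n_points + 2)[1:-1]
    if dist.ppf is None:
        raise InvalidParameterError("unbounded support requires a quantile function")
    a = float(np.atleast_1d(dist.ppf(TAIL_PROB))[0])
    b = float(np.atleast_1d(dist.ppf(1 - TAIL_PROB))[0])
    return np.linspace(a, b, n_points)


def read_samples(path, delimiter=None) -> np.ndarray:
    """Read a single-column sample file (optional header; NA/blanks rejected)."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if delimiter is not None:
                token = token.split(delimiter)[0].strip()
            if token == "":
                raise InvalidInputError(f"blank line at {path}:{lineno}")
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise InvalidInputError(
                    f"non-numeric value {token!r} at {path}:{lineno}"
                ) from None
    return np.asarray(values, dtype=float)
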
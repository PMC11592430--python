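"""The derangetropy functional and its basic analytic properties.

The derangetropy of a distribution with density f and CDF F is the density

    rho[f](x) = (24/(pi*e)) * sin(pi*F(x)) * F(x)^F(x) * (1-F(x))^(1-F(x)) * f(x),

a valid probability density describing how informational content is spread
over the support of f.  Three algebraically equivalent forms are exposed (the
defining product form, the Bernoulli-entropy form with exp(-H_B(F)), and the
Gamma-function form via Euler's reflection formula); keeping all three
separate gives a strong internal consistency check.

Conventions: natural logarithms throughout; 0^0 = 1 and H_B(0) = H_B(1) = 0,
so rho is exactly 0 wherever F is 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.special import gamma as _gamma
from scipy.special import xlogy

from .distributions import DistributionSpec, evaluation_grid
from .exceptions import DomainError, NumericalIntegrationError

__all__ = [
    "NORMALIZATION_CONSTANT",
    "binary_entropy",
    "derangetropy",
    "derangetropy_entropy_form",
    "derangetropy_gamma_form",
    "derangetropy_derivative",
    "normalization_check",
    "mode_of_derangetropy",
    "DerangetropyCurve",
    "write_curve_tsv",
]

#: The normalizing constant 24/(pi*e) that makes rho a probability density.
NORMALIZATION_CONSTANT = 24.0 / (np.pi * np.e)

# Clipping bounds for F inside logs/powers: purely a floating-point guard
# (0^0 = 1 is the mathematical convention); exact zeros are enforced after.
_F_LO, _F_HI = 1e-300, 1.0 - 1e-16


def binary_entropy(p):
    """Shannon entropy (nats) of a Bernoulli trial with success probability p.

    H_B(p) = -p*log(p) - (1-p)*log(1-p), with the convention 0*log(0) = 0.
    Symmetric about 1/2, maximal there (log 2).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("binary_entropy requires p in [0, 1]")
    out = -xlogy(p, p) - xlogy(1.0 - p, 1.0 - p)
    return out if out.ndim else float(out)


def _self_weight(F):
    """F^F * (1-F)^(1-F) with the 0^0 = 1 convention, via direct powers."""
    Fc = np.clip(F, _F_LO, _F_HI)
    return Fc**Fc * (1.0 - Fc) ** (1.0 - Fc)


def _finalize(values, F, scalar):
    """Zero out boundary points (sin(pi*F) = 0 there) and restore shape."""
    values = np.where((F <= 0.0) | (F >= 1.0), 0.0, values)
    values = np.maximum(values, 0.0)
    return float(values) if scalar else values


def derangetropy(dist: DistributionSpec, x):
    """Evaluate rho[f](x) in the defining product form."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    F = np.atleast_1d(np.asarray(dist.cdf(x), dtype=float))
    f = np.atleast_1d(np.asarray(dist.pdf(x), dtype=float))
    with np.errstate(invalid="ignore"):  # 0 * inf at heavy-boundary edges
        vals = (
            NORMALIZATION_CONSTANT
            * np.sin(np.pi * np.clip(F, 0, 1))
            * _self_weight(F)
            * f
        )
    vals = _finalize(vals, F, False)
    return float(vals[0]) if scalar else vals


def derangetropy_entropy_form(dist: DistributionSpec, x):
    """rho via the Fourier-type form (24/(pi*e))*sin(pi*F)*exp(-H_B(F))*f."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    F = np.atleast_1d(np.asarray(dist.cdf(x), dtype=float))
    f = np.atleast_1d(np.asarray(dist.pdf(x), dtype=float))
    with np.errstate(invalid="ignore"):
        vals = (
            NORMALIZATION_CONSTANT
            * np.sin(np.pi * np.clip(F, 0, 1))
            * np.exp(-binary_entropy(np.clip(F, 0, 1)))
            * f
        )
    vals = _finalize(vals, F, False)
    return float(vals[0]) if scalar else vals


def derangetropy_gamma_form(dist: DistributionSpec, x):
    """rho via Euler's reflection formula sin(pi*z) = pi/(Gamma(z)Gamma(1-z)).

    Returns (24/e) * [Gamma(F)Gamma(1-F)]^(-1) * F^F (1-F)^(1-F) * f on the
    interior, and 0 at F in {0, 1} (the continuity limit; the reflection
    formula itself requires non-integer argument).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    F = np.atleast_1d(np.asarray(dist.cdf(x), dtype=float))
    f = np.atleast_1d(np.asarray(dist.pdf(x), dtype=float))
    Fc = np.clip(F, _F_LO, _F_HI)
    with np.errstate(over="ignore"):
        refl = 1.0 / (_gamma(Fc) * _gamma(1.0 - Fc))  # = sin(pi F)/pi
    refl = np.where(np.isfinite(refl), refl, 0.0)
    with np.errstate(invalid="ignore"):
        vals = (24.0 / np.e) * refl * _self_weight(F) * f
    vals = _finalize(vals, F, False)
    return float(vals[0]) if scalar else vals


def derangetropy_derivative(dist: DistributionSpec, x):
    """d rho/dx at interior points, in chain-rule-complete form.

    d/dx rho = rho * [ (pi*cot(pi*F) + log(F/(1-F))) * f + f'/f ].
    Requires 0 < F(x) < 1 and f(x) > 0; the density derivative comes from the
    DistributionSpec (closed form for analytic families).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    F = np.asarray(dist.cdf(xv), dtype=float)
    f = np.asarray(dist.pdf(xv), dtype=float)
    if np.any((F <= 0.0) | (F >= 1.0) | (f <= 0.0)):
        raise DomainError("derivative defined only where 0 < F < 1 and f > 0")
    if dist.pdf_deriv is None:
        raise DomainError("distribution carries no density derivative")
    fp = np.asarray(dist.pdf_deriv(xv), dtype=float)
    rho = derangetropy(dist, xv)
    bracket = (np.pi / np.tan(np.pi * F) + np.log(F / (1.0 - F))) * f + fp / f
    out = rho * bracket
    return float(out[0]) if scalar else out


def normalization_check(dist: DistributionSpec) -> float:
    """Total mass of rho by adaptive quadrature over the support (should be 1)."""
    lo, hi = dist.support
    with np.errstate(all="ignore"):
        mass, err, info, *msg = integrate.quad(
            lambda t: derangetropy(dist, t),
            lo,
            hi,
            limit=400,
            epsabs=1e-10,
            epsrel=1e-10,
            points=[dist.median] if np.isfinite(lo) and np.isfinite(hi) else None,
            full_output=True,
        )
    if msg and err > 1e-6:
        raise NumericalIntegrationError(
            f"quadrature did not converge: estimate={mass}, abserr={err}, {msg[0]}"
        )
    return float(mass)


def mode_of_derangetropy(dist: DistributionSpec, n_scan: int = 2048) -> float:
    """Argmax of rho: coarse grid scan refined by bounded golden-section."""
    grid = evaluation_grid(dist, n_scan)
    vals = derangetropy(dist, grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -derangetropy(dist, float(t)),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


@dataclass
class DerangetropyCurve:
    """A derangetropy density evaluated on a grid, with its running CDF.

    ``level`` is the recursion depth n (level 1 = one application of the
    functional to the base distribution); ``cdf_values`` holds G^(n).
    """

    grid: np.ndarray
    values: np.ndarray
    level: int
    cdf_values: np.ndarray
    source: DistributionSpec = field(repr=False)

    def mass(self) -> float:
        """Trapezoid mass of the curve (unit, within quadrature tolerance)."""
        return float(np.trapezoid(self.values, self.grid))

    def mean(self) -> float:
        return float(np.trapezoid(self.values * self.grid, self.grid))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.trapezoid(self.values * (self.grid - mu) ** 2, self.grid))

    def validate(self, mass_tol: float = 1e-4) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("curve values must be non-negative")
        if abs(self.mass() - 1.0) > mass_tol:
            raise ValueError(f"curve mass {self.mass()} deviates from 1")
        if np.any(np.diff(self.cdf_values) < -1e-12) or np.any(
            (self.cdf_values < -1e-12) | (self.cdf_values > 1 + 1e-12)
        ):
            raise ValueError("cdf_values must be non-decreasing within [0, 1]")


def write_curve_tsv(curve: DerangetropyCurve, path, long_format: bool = False) -> None:
    """Write a curve as TSV: (x, rho) or long-format (x, rho, level)."""
    with open(path, "w") as fh:
        if long_format:
            fh.write("x\trho\tlevel\n")
            for x, r in zip(curve.grid, curve.values):
                fh.write(f"{x:.12g}\t{r:.12g}\t{curve.level}\n")
        else:
            fh.write("x\trho\n")
            for x, r in zip(curve.grid, curve.values):
                fh.write(f"{x:.12g}\t{r:.12g}\n")
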
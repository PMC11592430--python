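"""Informational-energy decomposition of the derangetropy log-density.

Taking logs of the derangetropy density splits it into two interpretable
pieces plus a constant:

    log rho = log sin(pi*F) - H_B(F) + log f + C,        C = log(24/(pi*e))

The *modulation energy* -log sin(pi*F) measures the effort to maintain order
(diverging at the support boundaries); the *structural energy*
H_B(F) - log f measures disorder.  Their sum, the total informational
energy, equals -log rho + C, and its interior minima are the equilibrium
points of the information landscape.  For the uniform(0, 1) base both
derivatives of the total energy have closed forms, used here both as the
primary route and as a cross-check for the numerical path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NORMALIZATION_CONSTANT, binary_entropy, derangetropy
from .distributions import DistributionSpec, evaluation_grid
from .exceptions import DomainError

__all__ = [
    "ENERGY_CONSTANT",
    "EnergyProfile",
    "EquilibriumReport",
    "energy_profile",
    "total_energy_derivative_uniform",
    "total_energy_second_derivative_uniform",
    "find_equilibria",
    "write_energy_tsv",
]

#: C = log(24/(pi*e)), the additive constant in the energy decomposition.
ENERGY_CONSTANT = float(np.log(NORMALIZATION_CONSTANT))


def _atanh(z):
    # atanh(z) = 0.5*log((1+z)/(1-z))
    z = np.asarray(z, dtype=float)
    return 0.5 * np.log((1.0 + z) / (1.0 - z))


@dataclass
class EnergyProfile:
    """Modulation, structural and total informational energies on a grid."""

    grid: np.ndarray
    modulation: np.ndarray
    structural: np.ndarray
    total: np.ndarray
    constant: float = ENERGY_CONSTANT


@dataclass
class EquilibriumReport:
    """An interior critical point of the total informational energy."""

    location: float
    first_derivative: float
    second_derivative: float
    classification: str  # "minimum" | "maximum" | "boundary-divergent"


def energy_profile(dist: DistributionSpec, grid) -> EnergyProfile:
    """Evaluate the three energies on a strictly increasing interior grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise DomainError("grid must be strictly increasing")
    F = np.asarray(dist.cdf(grid), dtype=float)
    f = np.asarray(dist.pdf(grid), dtype=float)
    if np.any((F <= 0.0) | (F >= 1.0)):
        raise DomainError("energies diverge where F(x) is 0 or 1; use interior points")
    with np.errstate(divide="ignore"):
        modulation = -np.log(np.sin(np.pi * F))
        structural = binary_entropy(F) - np.log(f)
    return EnergyProfile(
        grid=grid,
        modulation=modulation,
        structural=structural,
        total=modulation + structural,
    )


def total_energy_derivative_uniform(x):
    """Closed-form dE_total/dx for the uniform(0, 1) base.

    -pi*cot(pi*x) + 2*atanh(1 - 2x); antisymmetric about x = 1/2, whose root
    is the unique interior equilibrium.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise DomainError("closed form defined on the open interval (0, 1)")
    out = -np.pi / np.tan(np.pi * x) + 2.0 * _atanh(1.0 - 2.0 * x)
    return out if out.ndim else float(out)


def total_energy_second_derivative_uniform(x):
    """Closed-form d^2 E_total/dx^2 for the uniform(0, 1) base.

    Differentiating the first derivative -pi*cot(pi*x) + 2*atanh(1-2x) gives

        pi^2*csc^2(pi*x) - 1/(x*(1-x)),

    because d/dx [2*atanh(1-2x)] = -1/(x*(1-x)) (the binary entropy is
    concave).  The expression is strictly positive on (0, 1) — from
    sin^2(pi*x) <= pi^2*x*(1-x) — so the equilibrium at x = 1/2 is a
    minimum, with curvature pi^2 - 4 there; it diverges like 1/x^2 toward
    both boundaries.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise DomainError("closed form defined on the open interval (0, 1)")
    out = np.pi**2 / np.sin(np.pi * x) ** 2 - 1.0 / (x * (1.0 - x))
    return out if out.ndim else float(out)


def _total_energy_fn(dist: DistributionSpec):
    def Et(x):
        rho = derangetropy(dist, float(x))
        if rho <= 0:
            raise DomainError(f"total energy undefined at x={x} (rho = 0)")
        return -np.log(rho) + ENERGY_CONSTANT

    return Et


def _bisect(fn, a, b, xtol=1e-12, maxit=200):
    fa, fb = fn(a), fn(b)
    if fa == 0:
        return a
    if fb == 0:
        return b
    for _ in range(maxit):
        mid = 0.5 * (a + b)
        fm = fn(mid)
        if fm == 0 or (b - a) < xtol:
            return mid
        if (fa < 0) == (fm < 0):
            a, fa = mid, fm
        else:
            b, fb = mid, fm
    return 0.5 * (a + b)


def find_equilibria(dist: DistributionSpec, n_scan: int = 2048) -> list[EquilibriumReport]:
    """Interior critical points of the total energy, classified by curvature.

    The first derivative is scanned for sign changes on an interior grid and
    each bracket is refined by bisection.  For the uniform(0, 1) base the
    closed-form derivatives are used; otherwise central differences of
    -log rho + C with step equal to the grid spacing.
    """
    is_unit_uniform = dist.name == "uniform" and dist.params == (0.0, 1.0)
    grid = evaluation_grid(dist, n_scan)
    h = float(np.min(np.diff(grid)))

    if is_unit_uniform:
        dE = lambda x: float(total_energy_derivative_uniform(x))  # noqa: E731
        d2E = lambda x: float(total_energy_second_derivative_uniform(x))  # noqa: E731
    else:
        Et = _total_energy_fn(dist)
        dE = lambda x: (Et(x + h) - Et(x - h)) / (2 * h)  # noqa: E731
        d2E = lambda x: (Et(x + h) - 2 * Et(x) + Et(x - h)) / h**2  # noqa: E731

    # keep x +/- h inside the grid span for the finite-difference path
    xs = grid[2:-2]
    out: list[EquilibriumReport] = []
    vals = np.array([dE(x) for x in xs])
    sign = np.sign(vals)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        root = _bisect(dE, float(xs[i]), float(xs[i + 1]))
        curv = d2E(root)
        out.append(
            EquilibriumReport(
                location=float(root),
                first_derivative=float(dE(root)),
                second_derivative=float(curv),
                classification="minimum" if curv > 0 else "maximum",
            )
        )
    return out


def write_energy_tsv(profile: EnergyProfile, path) -> None:
    """Four-column TSV (x, modulation, structural, total); inf spelled 'inf'."""

    def fmt(v):
        return "inf" if np.isinf(v) else f"{v:.12g}"

    with open(path, "w") as fh:
        fh.write("x\tmodulation\tstructural\ttotal\n")
        for x, m, s, t in zip(
            profile.grid, profile.modulation, profile.structural, profile.total
        ):
            fh.write(f"{x:.12g}\t{fmt(m)}\t{fmt(s)}\t{fmt(t)}\n")
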
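"""Closed-form theory of the lattice model and the critical boundary.

On the Moore lattice the base reproductive number of a strain (beta, tau_I)
is R0 = 8(1 - exp(-beta*tau_I)): during its infectious period a host makes
an infection attempt on each of its 8 neighbours at rate beta, and R0
saturates at the neighbourhood size.  In one dimension the frequency at
which a site emits/receives infection waves is
w_1D = 1/(1/beta + tau_I + tau_R): the cycle time is the typical time to be
infected (1/beta) plus the infectious and recovered periods.

The critical boundary separating the disordered phase (selection for larger
R0) from the self-structured wave phase (selection for larger w) is where
the two selection gradients balance, R0 = c * w_1D with c a
dimensionalization constant.  With the first-order approximation
R0 ~ n*beta*tau_I this yields the closed form

    beta(tau_I) = (c/n - tau_I) / (tau_I * (tau_I + tau_R))

whose leading term for small tau_I is beta ~ c/(n*tau_I*tau_R), i.e. a
hyperbola of constant R0 ~ c (for tau_R = 1).  ``boundary_exact`` instead
solves R0 = c*w_1D with the full exponential R0 numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .core import StrainTraits

__all__ = ["TheoryParams", "exact_r0", "first_order_r0", "w_one_d",
           "MutantNeighbourhood", "mutant_neighbourhood",
           "boundary_approx", "boundary_approx_leading", "boundary_exact"]

# fitted trade-off constant of the evolved hyperbola tau_I = c/(8 beta)
C_EV = 6.623


@dataclass(frozen=True)
class TheoryParams:
    """Neighbourhood size, dimensionalization constant and recovery period."""

    n: int = 8
    c: float = C_EV
    tau_R: float = 1.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.tau_R < 0:
            raise ValueError(f"tau_R must be >= 0, got {self.tau_R}")


def exact_r0(beta, tau_I, n: int = 8):
    """Base reproductive number R0 = n(1 - exp(-beta*tau_I)); independent of tau_R."""
    beta = np.asarray(beta, dtype=float)
    tau_I = np.asarray(tau_I, dtype=float)
    if (beta < 0).any() or (tau_I < 0).any():
        raise ValueError("beta and tau_I must be >= 0")
    out = n * (1.0 - np.exp(-beta * tau_I))
    return float(out) if out.ndim == 0 else out


def first_order_r0(beta, tau_I, n: int = 8, order: int = 2):
    """Small-(beta*tau_I) expansion of R0: n*x - (n/2)*x^2 (order 2) or n*x (order 1)."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    x = np.asarray(beta, dtype=float) * np.asarray(tau_I, dtype=float)
    out = n * x if order == 1 else n * x - (n / 2.0) * x ** 2
    return float(out) if np.ndim(out) == 0 else out


def w_one_d(beta, tau_I, tau_R):
    """1D wave-emission frequency w = 1/(1/beta + tau_I + tau_R)."""
    beta = np.asarray(beta, dtype=float)
    if (beta <= 0).any():
        raise ValueError("beta must be > 0 (cycle time diverges)")
    tau_I = np.asarray(tau_I, dtype=float)
    tau_R = np.asarray(tau_R, dtype=float)
    if (tau_I < 0).any() or (tau_R < 0).any():
        raise ValueError("periods must be >= 0")
    out = 1.0 / (1.0 / beta + tau_I + tau_R)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MutantNeighbourhood:
    """The focal strain and its four one-step mutants with their R0 and w_1D.

    Labels: "++" = (beta+d, tau+d), "+-" = (beta+d, tau-d), etc.; "0" is the
    focal strain.
    """

    strains: dict
    r0: dict
    w1d: dict

    def r0_ordering(self):
        """Labels sorted by decreasing R0."""
        return sorted(self.r0, key=self.r0.get, reverse=True)

    def w1d_ordering(self):
        """Labels sorted by decreasing w_1D."""
        return sorted(self.w1d, key=self.w1d.get, reverse=True)


def mutant_neighbourhood(s0: StrainTraits, d_beta: float, d_tau: float,
                         tau_R: float = 1.0) -> MutantNeighbourhood:
    """Build s_{+-}-style one-step mutants of s0 and rank them.

    For beta > tau_I and small increments the R0 ranking is
    ++ > -+ > 0 > +- > -- while the w_1D ranking is +- > -- > 0 > ++ > -+;
    both middle pairs swap when beta < tau_I.
    """
    if d_beta < 0 or d_tau < 0:
        raise ValueError("increments must be >= 0")
    if s0.beta - d_beta <= 0 or s0.tau_I - d_tau <= 0:
        raise ValueError("increments produce non-positive mutant traits")
    strains = {
        "0": s0,
        "++": StrainTraits(s0.beta + d_beta, s0.tau_I + d_tau),
        "+-": StrainTraits(s0.beta + d_beta, s0.tau_I - d_tau),
        "-+": StrainTraits(s0.beta - d_beta, s0.tau_I + d_tau),
        "--": StrainTraits(s0.beta - d_beta, s0.tau_I - d_tau),
    }
    r0 = {k: exact_r0(s.beta, s.tau_I) for k, s in strains.items()}
    w1d = {k: w_one_d(s.beta, s.tau_I, tau_R) for k, s in strains.items()}
    return MutantNeighbourhood(strains, r0, w1d)


def boundary_approx(tau_I, params: TheoryParams):
    """First-order critical boundary beta = (c/n - tau_I)/(tau_I (tau_I + tau_R))."""
    tau_I = np.asarray(tau_I, dtype=float)
    if (tau_I <= 0).any() or (tau_I > params.c / params.n).any():
        raise ValueError(f"tau_I must lie in (0, c/n] = (0, {params.c / params.n}]")
    out = (params.c / params.n - tau_I) / (tau_I * (tau_I + params.tau_R))
    return float(out) if out.ndim == 0 else out


def boundary_approx_leading(tau_I, params: TheoryParams):
    """Leading small-tau_I term of the boundary, beta = c/(n tau_I tau_R)."""
    tau_I = np.asarray(tau_I, dtype=float)
    if (tau_I <= 0).any():
        raise ValueError("tau_I must be > 0")
    if params.tau_R == 0:
        raise ValueError("leading-order form diverges for tau_R = 0")
    out = params.c / (params.n * tau_I * params.tau_R)
    return float(out) if out.ndim == 0 else out


def boundary_exact(tau_I: float, params: TheoryParams,
                   beta_lo: float = 1e-6, beta_hi: float = 1e3) -> float:
    """Solve n(1 - exp(-beta*tau_I)) = c * w_1D(beta, tau_I, tau_R) for beta.

    The bracket [beta_lo, beta_hi] is scanned geometrically for a sign
    change, then refined by Brent's method to relative tolerance ~1e-12.
    """
    tau_I = float(tau_I)
    if tau_I <= 0:
        raise ValueError("tau_I must be > 0")

    def f(beta):
        return (exact_r0(beta, tau_I, n=params.n)
                - params.c * w_one_d(beta, tau_I, params.tau_R))

    grid = np.geomspace(beta_lo, beta_hi, 200)
    vals = np.array([f(b) for b in grid])
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if idx.size == 0:
        zero = np.nonzero(vals == 0.0)[0]
        if zero.size:
            return float(grid[zero[0]])
        raise ValueError(
            f"no sign change of R0 - c*w_1D for beta in [{beta_lo}, {beta_hi}] "
            f"at tau_I={tau_I}, c={params.c}, tau_R={params.tau_R}")
    a, b = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(f, a, b, xtol=1e-15, rtol=8.9e-16))
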
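"""Host movement: Toffoli-Margolus block diffusion and long-range contacts.

Local diffusion is emulated by rotating 2x2 blocks of sites a quarter turn
on alternating even/odd partitions.  Each application moves every host one
lattice spacing, so a diffusion coefficient D = Gamma (dx)^2 with dx = 1 is
obtained by applying the mixing every Gamma = 1/(D*dt) sweeps.

Long-range contacts replace, with probability p_long per contact, one of the
8 Moore contacts of a susceptible site by a uniformly random lattice site.
By default the replacement is annealed (redrawn every sweep); a quenched
mode rewires the contact map once at setup instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import LatticeState

__all__ = ["MobilityParams", "margolus_mix", "apply_mixing_schedule",
           "rewire_quenched"]


@dataclass(frozen=True)
class MobilityParams:
    """Diffusion coefficient and long-range contact probability.

    D is in units of (lattice spacing)^2 per unit time; p_long is the
    probability that any single contact of a susceptible site reaches a
    uniformly random site instead of the Moore neighbour.
    """

    D: float = 0.0
    p_long: float = 0.0
    long_range_mode: str = "annealed"  # or "quenched"

    def __post_init__(self):
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if not (0.0 <= self.p_long <= 1.0):
            raise ValueError(f"p_long must be in [0, 1], got {self.p_long}")
        if self.long_range_mode not in ("annealed", "quenched"):
            raise ValueError(f"unknown long_range_mode {self.long_range_mode!r}")

    @property
    def quenched(self) -> bool:
        return self.long_range_mode == "quenched"

    def gamma_period(self, dt: float) -> int:
        """Mixing period Gamma = round(1/(D*dt)) in sweeps; 0 when D == 0."""
        if self.D == 0:
            return 0
        period = int(round(1.0 / (self.D * dt)))
        return max(1, period)

    def validate(self, shape=None) -> None:
        if self.D > 0 and shape is not None:
            if shape[0] % 2 or shape[1] % 2:
                raise ValueError(
                    f"Margolus mixing needs even lattice sides, got {shape}")


def apply_mixing_schedule(step_index: int, params: MobilityParams,
                          dt: float) -> bool:
    """True exactly every Gamma-th sweep (1-based index); never when D == 0."""
    if params.D == 0:
        return False
    period = params.gamma_period(dt)
    return step_index >= 1 and step_index % period == 0


def margolus_mix(lattice: LatticeState, phase: str,
                 seed: int | None = None) -> LatticeState:
    """One Margolus mixing pass as a pure function (for tests and tools).

    ``phase`` is "even" (blocks anchored at (0,0)) or "odd" (anchored at
    (1,1)).  Each block rotates a quarter turn, clockwise or counter-
    clockwise with probability 1/2, carrying the full site payload.
    """
    if lattice.shape[0] % 2 or lattice.shape[1] % 2:
        raise ValueError(f"Margolus mixing needs even lattice sides, got {lattice.shape}")
    if phase not in ("even", "odd"):
        raise ValueError(f"phase must be 'even' or 'odd', got {phase!r}")
    if seed is not None:
        _kernels.seed_rng(int(seed))
    out = lattice.copy()
    _kernels.margolus(out.state, out.timer, out.beta, out.tau,
                      0 if phase == "even" else 1)
    return out


def rewire_quenched(nbr_r: np.ndarray, nbr_c: np.ndarray, p_long: float,
                    rng: np.random.Generator) -> tuple:
    """Rewire each directed contact once, with probability p_long, to a
    uniformly random site other than the focal site."""
    nr, nc, _ = nbr_r.shape
    nbr_r = nbr_r.copy()
    nbr_c = nbr_c.copy()
    mask = rng.random(nbr_r.shape) < p_long
    ii = np.broadcast_to(np.arange(nr)[:, None, None], nbr_r.shape)
    jj = np.broadcast_to(np.arange(nc)[None, :, None], nbr_r.shape)
    n_rw = int(mask.sum())
    if n_rw:
        rr = rng.integers(0, nr, size=n_rw)
        cc = rng.integers(0, nc, size=n_rw)
        self_hit = (rr == ii[mask]) & (cc == jj[mask])
        while self_hit.any():
            k = int(self_hit.sum())
            rr[self_hit] = rng.integers(0, nr, size=k)
            cc[self_hit] = rng.integers(0, nc, size=k)
            self_hit = (rr == ii[mask]) & (cc == jj[mask])
        nbr_r[mask] = rr
        nbr_c[mask] = cc
    return nbr_r, nbr_c
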